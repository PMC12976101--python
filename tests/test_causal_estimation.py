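"""Imputation, propensity weighting, the proportional-odds fitter and
Rubin pooling, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ttehta.causal_estimation import (DegenerateFitError, SeparationError,
                                      compare_populations, compute_iptw,
                                      estimate_effect, fit_propensity,
                                      fit_weighted_ordinal, impute_pmm,
                                      pool_rubin, reconstruct_count,
                                      reconstruct_counts,
                                      standardized_mean_differences)

# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------


def test_impute_identity_without_missingness():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.1, 0.2, 0.3],
                       "treated": [0, 1, 0], "eular": [0, 1, 2]})
    out = impute_pmm(df, ["a", "b"], m=3, seed=1)
    assert len(out) == 3
    for comp in out:
        pd.testing.assert_frame_equal(comp, df)


def test_pmm_imputes_from_observed_donor_pool():
    rng = np.random.default_rng(0)
    n = 60
    df = pd.DataFrame({
        "x": rng.normal(size=n),
        "mtx": np.tile([5.0, 10.0, 15.0], n // 3),
        "treated": rng.integers(0, 2, n),
        "eular": rng.integers(0, 3, n),
    })
    df.loc[0, "mtx"] = np.nan
    out = impute_pmm(df, ["x", "mtx"], m=5, seed=2, k_pmm=3)
    for comp in out:
        assert comp.loc[0, "mtx"] in {5.0, 10.0, 15.0}
        # observed values untouched
        assert (comp["mtx"].iloc[1:] == df["mtx"].iloc[1:]).all()


def test_pmm_recovers_means_under_mar():
    """Missing-at-random masking keyed on an always-observed covariate:
    pooled imputed means agree with the complete-data means."""
    rng = np.random.default_rng(3)
    n = 3000
    z = rng.normal(size=n)
    x = 10 + 2 * z + rng.normal(0, 1, n)
    df_complete = pd.DataFrame({"z": z, "x": x,
                                "treated": rng.integers(0, 2, n),
                                "eular": rng.integers(0, 3, n)})
    df = df_complete.copy()
    mask = rng.random(n) < expit(z)          # MAR via z
    df.loc[mask, "x"] = np.nan
    out = impute_pmm(df, ["z", "x"], m=10, seed=4)
    pooled = np.mean([c["x"].mean() for c in out])
    mc_se = df_complete["x"].std() / np.sqrt(n)
    assert abs(pooled - df_complete["x"].mean()) < 4 * mc_se


def test_fully_missing_covariate_is_an_error():
    df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
    with pytest.raises(ValueError, match="a"):
        impute_pmm(df, ["a", "b"], m=2, seed=0)


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------


def _toy_logistic(n, beta, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(beta)))
    p = expit(X @ np.asarray(beta))
    t = (rng.random(n) < p).astype(int)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(len(beta))])
    df["treated"] = t
    return df


def test_propensity_null_case():
    df = _toy_logistic(20000, [0.0, 0.0], seed=1)
    fit = fit_propensity(df, ["x0", "x1"])
    assert np.allclose(fit.coefficients[["x0", "x1"]], 0, atol=0.05)
    assert fit.scores.mean() == pytest.approx(df["treated"].mean(), abs=0.01)


def test_propensity_recovers_known_coefficients():
    beta = [0.5, -0.3, 0.2]
    df = _toy_logistic(20000, beta, seed=2)
    fit = fit_propensity(df, ["x0", "x1", "x2"])
    se = 1.0 / np.sqrt(len(df) * 0.25)   # conservative logistic-scale bound
    for b, name in zip(beta, ("x0", "x1", "x2")):
        assert abs(fit.coefficients[name] - b) < 3 * max(se, 0.02)


def test_propensity_matches_hand_rolled_irls():
    """Eight-row toy fit vs an independent iteratively-reweighted
    least-squares implementation."""
    df = pd.DataFrame({"x0": [0.5, -1.2, 0.55, 2.0, -0.7, 1.1, -0.2, 0.9],
                       "x1": [1.0, 0.2, 0.95, 0.3, -1.5, 0.8, 0.1, -0.9],
                       "treated": [1, 1, 0, 1, 0, 1, 0, 0]})
    fit = fit_propensity(df, ["x0", "x1"])

    Xs = (df[["x0", "x1"]] - df[["x0", "x1"]].mean()) / df[["x0", "x1"]].std(ddof=0)
    X = np.column_stack([np.ones(8), Xs.to_numpy()])
    y = df["treated"].to_numpy(dtype=float)
    b = np.zeros(3)
    for _ in range(60):
        p = expit(X @ b)
        Wd = p * (1 - p)
        H = X.T @ (Wd[:, None] * X)
        b = b + np.linalg.solve(H, X.T @ (y - p))
    assert np.allclose(fit.scores, expit(X @ b), atol=1e-6)


def test_perfect_separation_raises_named_error():
    df = pd.DataFrame({"x0": np.r_[np.ones(20), -np.ones(20)],
                       "treated": np.r_[np.ones(20), np.zeros(20)].astype(int)})
    with pytest.raises(SeparationError):
        fit_propensity(df, ["x0"])


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def test_iptw_closed_forms():
    t = np.array([1, 0, 1, 0])
    w = compute_iptw(np.array([0.5, 0.5, 0.5, 0.5]), t).weights
    assert np.allclose(w, 2.0)
    w = compute_iptw(np.array([0.8, 0.8]), np.array([1, 0])).weights
    assert w[0] == pytest.approx(1.25)
    assert w[1] == pytest.approx(5.0)


def test_stabilized_weights_average_one_per_arm():
    rng = np.random.default_rng(5)
    e = rng.uniform(0.2, 0.8, 5000)
    t = (rng.random(5000) < e).astype(int)
    w = compute_iptw(e, t, stabilized=True).weights
    assert np.mean(w[t == 1]) == pytest.approx(1.0, abs=0.05)
    assert np.mean(w[t == 0]) == pytest.approx(1.0, abs=0.05)


def test_degenerate_scores_rejected():
    with pytest.raises(ValueError, match="truncation"):
        compute_iptw(np.array([0.0, 0.5]), np.array([1, 0]))


def test_truncation_caps_weights():
    rng = np.random.default_rng(6)
    e = rng.uniform(0.01, 0.99, 2000)
    t = (rng.random(2000) < e).astype(int)
    res = compute_iptw(e, t, truncate_percentile=1.0)
    assert res.weights.max() <= res.cap[1] + 1e-12


def test_weighting_improves_balance():
    from ttehta.synthetic_registry import SyntheticConfig, generate_cohort
    from ttehta.trial_emulation import ProtocolConfig, emulate
    cohort = generate_cohort(SyntheticConfig(n_patients=20000, seed=33,
                                             missingness_rates={}))
    dataset, _ = emulate(cohort, ProtocolConfig())
    fit = fit_propensity(dataset)
    w = compute_iptw(fit, dataset["treated"]).weights
    smd_after = standardized_mean_differences(dataset, fit.covariates,
                                              weights=w).abs()
    smd_before = fit.smd_unweighted.abs()
    improved = (smd_after < smd_before) | (smd_before < 0.02)
    assert improved.mean() >= 0.9
    assert smd_after.max() < 0.1


# ---------------------------------------------------------------------------
# proportional-odds fitter
# ---------------------------------------------------------------------------


def _table_from_po(alpha1, alpha2, beta, n0=1000, n1=1000):
    """Exact expected counts under a proportional-odds model."""
    rows = []
    for t, n in ((0, n0), (1, n1)):
        s1, s2 = expit(alpha1 + beta * t), expit(alpha2 + beta * t)
        rows.append(np.array([1 - s1, s1 - s2, s2]) * n)
    return np.array(rows)


def _expand(table):
    y = np.array([0, 1, 2, 0, 1, 2])
    t = np.array([0, 0, 0, 1, 1, 1])
    w = table.ravel()
    return y, t, w


def test_po_fit_recovers_self_consistent_construction():
    table = _table_from_po(-0.8, -2.0, 0.5)
    y, t, w = _expand(table)
    est = fit_weighted_ordinal(y, t, weights=w, robust=False)
    assert est.beta == pytest.approx(0.5, abs=1e-6)
    assert est.alpha_moderate == pytest.approx(-0.8, abs=1e-6)
    assert est.alpha_good == pytest.approx(-2.0, abs=1e-6)


def test_po_fit_matches_grid_search_likelihood_oracle():
    """Zooming grid search over (alpha1, alpha2, beta) as an independent
    maximum-likelihood oracle on a small integer table."""
    table = np.array([[70.0, 20.0, 10.0], [45.0, 30.0, 25.0]])
    y, t, w = _expand(table)
    est = fit_weighted_ordinal(y, t, weights=w, robust=False)

    def nll(c1, c2, b):
        out = 0.0
        for ti in (0, 1):
            s1, s2 = expit(c1 + b * ti), expit(c2 + b * ti)
            p = np.clip([1 - s1, s1 - s2, s2], 1e-12, None)
            out -= table[ti] @ np.log(p)
        return out

    center = np.array([0.0, -1.0, 0.5])
    width = 2.0
    for _ in range(8):
        grids = [np.linspace(c - width, c + width, 13) for c in center]
        best, arg = np.inf, center
        for c1 in grids[0]:
            for c2 in grids[1]:
                for b in grids[2]:
                    v = nll(c1, c2, b)
                    if v < best:
                        best, arg = v, np.array([c1, c2, b])
        center, width = arg, width / 4
    assert est.beta == pytest.approx(center[2], abs=1e-4)
    assert est.alpha_moderate == pytest.approx(center[0], abs=1e-4)


def test_po_fit_matches_reference_implementation():
    """Unweighted fit vs statsmodels' ordinal regression."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel
    rng = np.random.default_rng(7)
    t = rng.integers(0, 2, 800)
    u = rng.random(800)
    s1, s2 = expit(-0.5 + 0.4 * t), expit(-1.6 + 0.4 * t)
    y = np.zeros(800, dtype=int)
    y[u < s1] = 1
    y[u < s2] = 2
    est = fit_weighted_ordinal(y, t)
    ref = OrderedModel(y, t[:, None], distr="logit").fit(method="bfgs", disp=0)
    assert est.beta == pytest.approx(ref.params[0], abs=1e-4)
    assert est.se == pytest.approx(ref.bse[0], rel=1e-3)


def test_degenerate_arm_raises():
    y = np.array([2, 2, 2, 0, 1, 2])
    t = np.array([1, 1, 1, 0, 0, 0])
    with pytest.raises(DegenerateFitError):
        fit_weighted_ordinal(y, t)


def test_estimate_interval_contains_point(emulated_5k):
    dataset, _ = emulated_5k
    est = estimate_effect(dataset, adjusted=True, m=1)
    assert est.ci_low <= est.beta <= est.ci_high
    assert est.odds_ratio > 0
    probs = est.response_probabilities()
    assert (probs["p_good"] <= probs["p_modplus"]).all()
    assert est.variance_method == "stacked_sandwich"


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------


def _est(beta, var):
    from ttehta.causal_estimation import OrdinalEffectEstimate
    return OrdinalEffectEstimate(beta=beta, se=np.sqrt(var), alpha_moderate=-1.0,
                                 alpha_good=-2.0, ci_low=beta - 1.96 * np.sqrt(var),
                                 ci_high=beta + 1.96 * np.sqrt(var))


def test_rubin_closed_form():
    pooled = pool_rubin([_est(0.2, 0.01), _est(0.4, 0.01)])
    assert pooled.beta == pytest.approx(0.3)
    assert pooled.se ** 2 == pytest.approx(0.01 + 1.5 * 0.02)
    assert pooled.m_imputations == 2


def test_rubin_degenerate_identical_estimates():
    pooled = pool_rubin([_est(0.25, 0.02)] * 4)
    assert pooled.beta == pytest.approx(0.25)
    assert pooled.se ** 2 == pytest.approx(0.02)
    assert pooled.diagnostics["between_variance"] == pytest.approx(0.0)


def test_rubin_single_imputation_warns():
    with pytest.warns(UserWarning):
        out = pool_rubin([_est(0.3, 0.01)])
    assert out.beta == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# population comparison & reconstruction
# ---------------------------------------------------------------------------


def test_identical_populations_give_or_one():
    est = compare_populations([50, 30, 20], [50, 30, 20])
    assert est.odds_ratio == pytest.approx(1.0, abs=1e-6)


def test_binary_collapse_matches_cross_product_odds_ratio():
    """Collapsing a hand table to good-vs-not reproduces the closed-form
    cross-product odds ratio, and the common proportional-odds ratio
    lies between the two cumulative-split odds ratios."""
    import statsmodels.api as sm
    a, b = np.array([60, 25, 15]), np.array([35, 30, 35])
    # 2x2 collapse on the good split, fitted as a binary logistic model
    y = np.array([0.0, 1.0, 0.0, 1.0])
    x = sm.add_constant(np.array([0.0, 0.0, 1.0, 1.0]))
    freq = np.array([a[0] + a[1], a[2], b[0] + b[1], b[2]])
    fit = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=freq).fit()
    crude = (b[2] * (a[0] + a[1])) / (a[2] * (b[0] + b[1]))
    assert np.exp(fit.params[1]) == pytest.approx(crude, rel=1e-8)

    est = compare_populations(a, b)
    or_split1 = ((b[1] + b[2]) / b[0]) / ((a[1] + a[2]) / a[0])
    or_split2 = crude
    lo, hi = sorted((or_split1, or_split2))
    assert lo <= est.odds_ratio <= hi


def test_reconstruction_arithmetic():
    assert reconstruct_count(0.650, 298) == 194
    assert reconstruct_count(0.0, 57) == 0
    for n, pm, pg in ((298, 0.65, 0.15), (1360, 0.215, 0.09), (7, 0.5, 0.25)):
        counts = reconstruct_counts(n, pm, pg)
        assert counts.sum() == n
        assert (counts >= 0).all()
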