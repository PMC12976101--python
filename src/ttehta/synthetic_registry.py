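"""Synthetic registry cohorts with known causal ground truth.

This module generates longitudinal cohorts shaped like a national
biologics register for rheumatoid arthritis: patients carry baseline
covariates, attend follow-up visits roughly every six months at which
DAS28 components and HAQ are recorded, and hold treatment episodes
(a failed first-line biologic, then either a second-line rituximab
course or a nonbiologic period).  Treatment assignment is confounded
through a logistic model in the covariates, and the EULAR response
outcome follows a proportional-odds model with a configurable true
treatment effect, so that downstream causal estimators can be validated
against known truth.

Ground-truth construction
-------------------------
The configured ``true_log_or`` is defined as the *marginal*
(population-averaged) proportional-odds log odds ratio over the eligible
population (baseline DAS28 > 3.2) — the quantity an IPTW-weighted
proportional-odds fit estimates.  Because the odds ratio is not
collapsible, the conditional coefficient used to draw individual
outcomes is calibrated internally: we solve for the conditional effect
whose implied marginal category distributions, projected onto the
proportional-odds family, return exactly ``true_log_or``.

The follow-up DAS28 is then sampled uniformly from the region of the
(baseline, follow-up) plane consistent with the drawn EULAR category,
which guarantees that re-classifying the stored scores reproduces the
generated category.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import expit, logit



__all__ = [
    "ConfigurationError",
    "RegistryValidationError",
    "SyntheticConfig",
    "RegistryCohort",
    "generate_cohort",
    "inject_missingness",
    "write_registry",
    "read_registry",
    "das28_composite",
    "calibrate_outcome_model",
]


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration is invalid."""


class RegistryValidationError(ValueError):
    """Raised when registry tables violate the documented schema."""


# DAS28 four-component composite (ESR version)
def das28_composite(tjc28, sjc28, esr, patient_global):
    """0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.70*ln(ESR) + 0.014*PGA."""
    return (0.56 * np.sqrt(tjc28) + 0.28 * np.sqrt(sjc28)
            + 0.70 * np.log(esr) + 0.014 * patient_global)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: analysis covariates carried in the patients table
COVARIATE_COLUMNS = [
    "female", "age_years", "disease_duration_years", "tjc28", "sjc28",
    "esr_mm_hr", "patient_global_0_100", "das28", "haq_0_3",
    "rheumatoid_factor_flag", "comorbidity_flag", "n_previous_dmards",
    "n_previous_biologics", "stop_reason_inefficacy_flag",
    "glucocorticoid_flag", "mtx_weekly_dose_mg",
]

ANTI_TNF_AND_ALLOWED = ("ABT", "ADA", "CTZ", "ETN", "GOL", "IFX", "TCZ")

_EPOCH = pd.Timestamp("2001-01-01")


def _default_assignment_coefficients() -> dict:
    # log-odds of receiving rituximab per covariate (continuous covariates
    # enter standardised); calibrated so the arms show register-like
    # imbalance: inefficacy-stop ~60% vs ~45%, DAS28 median shifted ~0.2
    return {
        "intercept": -0.90,
        "das28": 0.18,
        "disease_duration_years": 0.15,
        "stop_reason_inefficacy_flag": 0.65,
        "female": 0.18,
        "mtx_weekly_dose_mg": -0.25,
        "haq_0_3": -0.08,
        "age_years": -0.05,
        "glucocorticoid_flag": 0.15,
        "esr_mm_hr": 0.05,
    }


def _default_prognostic_coefficients() -> dict:
    # effect of covariates on the latent EULAR response scale (higher =
    # better response); overlaps with the assignment model to create
    # confounding by indication that masks the rituximab benefit
    return {
        "das28": -0.25,
        "haq_0_3": -0.25,
        "stop_reason_inefficacy_flag": -0.30,
        "disease_duration_years": -0.15,
        "age_years": -0.10,
        "mtx_weekly_dose_mg": 0.10,
        "female": -0.05,
    }


def _default_missingness_rates() -> dict:
    # per-covariate missingness probabilities, loosely shaped like the
    # availability pattern of a real register extract
    return {
        "disease_duration_years": 0.01,
        "tjc28": 0.10,
        "sjc28": 0.10,
        "esr_mm_hr": 0.14,
        "patient_global_0_100": 0.11,
        "haq_0_3": 0.04,
        "glucocorticoid_flag": 0.15,
        "mtx_weekly_dose_mg": 0.25,
    }


@dataclass
class SyntheticConfig:
    """Settings for the synthetic registry generator.

    ``true_log_or`` is the marginal proportional-odds treatment effect of
    rituximab versus nonbiologic therapy on the ordered EULAR outcome,
    over the eligible (DAS28 > 3.2) population.  The default corresponds
    to an odds ratio of 1.39.  ``control_response_targets`` are the
    marginal probabilities of at least a moderate, and of a good,
    response under nonbiologic therapy (defaults 0.174 / 0.066).
    """

    n_patients: int = 4000
    seed: int = 0
    assignment_coefficients: dict = field(default_factory=_default_assignment_coefficients)
    true_log_or: float = float(np.log(1.39))
    prognostic_coefficients: dict = field(default_factory=_default_prognostic_coefficients)
    control_response_targets: tuple = (0.174, 0.066)
    visit_interval_days: float = 183.0
    visit_jitter_days: float = 30.0
    measurement_jitter_days: float = 20.0
    missingness_rates: dict = field(default_factory=_default_missingness_rates)
    missing_followup_rate: float = 0.05
    mtx_coverage: float = 0.92
    prior_rtx_rate: float = 0.02
    rtx_gap_days: tuple = (0.0, 100.0)
    nbt_early_biologic_rate: float = 0.12   # new biologic < 20 weeks: fails persistence
    nbt_mid_biologic_rate: float = 0.03     # biologic in weeks 20-24: non-adherent
    nbt_late_rtx_rate: float = 0.10         # rituximab after follow-up: still adherent
    rtx_discontinue_rate: float = 0.15      # rituximab stopped before 24 weeks
    covariate_generators: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for col, rate in self.missingness_rates.items():
            rates = np.atleast_1d(np.asarray(rate, dtype=float))
            if np.any(rates < 0) or np.any(rates >= 1):
                raise ConfigurationError(
                    f"missingness rate for {col!r} must lie in [0, 1)")
        for name, (loc, scale) in self._covariate_settings().items():
            if scale <= 0:
                raise ConfigurationError(
                    f"covariate {name!r} has non-positive scale {scale}")
        for r in (self.missing_followup_rate, self.mtx_coverage,
                  self.prior_rtx_rate, self.nbt_early_biologic_rate,
                  self.nbt_mid_biologic_rate, self.nbt_late_rtx_rate,
                  self.rtx_discontinue_rate):
            if not 0 <= r <= 1:
                raise ConfigurationError("episode rates must lie in [0, 1]")
        if self.visit_interval_days <= 0 or self.visit_jitter_days < 0:
            raise ConfigurationError("visit spacing settings must be positive")

    def _covariate_settings(self) -> dict:
        # (location, scale) per continuous covariate; log-scale where noted
        base = {
            "age_years": (60.0, 11.0),
            "disease_duration_years": (np.log(14.5), 0.55),   # lognormal
            "tjc28": (np.log(9.0), 0.70),                      # lognormal
            "sjc28": (np.log(5.5), 0.65),                      # lognormal
            "esr_mm_hr": (np.log(34.0), 0.60),                 # lognormal
            "patient_global_0_100": (63.0, 22.0),
            "haq_0_3": (1.95, 0.60),
        }
        base.update(self.covariate_generators)
        return base


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class RegistryCohort:
    """Registry cohort as three keyed tables plus optional ground truth.

    ``patients`` carries one row per patient with baseline covariates and
    the observation window; ``visits`` one row per follow-up visit with
    DAS28 components; ``episodes`` one row per treatment episode.  All
    three are keyed by ``patient_id``.  ``truth`` (present for generated
    cohorts) records the assigned strategy, the generated EULAR category
    and the calibrated outcome-model parameters for test introspection.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    episodes: pd.DataFrame
    truth: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def validate(self) -> None:
        _validate_tables(self.patients, self.visits, self.episodes)

    def copy(self) -> "RegistryCohort":
        return RegistryCohort(
            self.patients.copy(), self.visits.copy(), self.episodes.copy(),
            None if self.truth is None else self.truth.copy(),
            dict(self.meta))

    def equals(self, other: "RegistryCohort") -> bool:
        for a, b in ((self.patients, other.patients),
                     (self.visits, other.visits),
                     (self.episodes, other.episodes)):
            if not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
                return False
        return True


# ---------------------------------------------------------------------------
# outcome-model calibration
# ---------------------------------------------------------------------------

_CALIBRATION_SAMPLE_SEED = 202406
_CALIBRATION_SAMPLE_SIZE = 40000
_calibration_cache: dict = {}


def _standardize(x, loc, scale):
    return (x - loc) / scale


def _draw_covariates(config: SyntheticConfig, rng: np.random.Generator,
                     n: int) -> pd.DataFrame:
    """Draw baseline covariates via a Gaussian copula over the continuous
    block (joint counts, ESR, patient global and HAQ are mutually
    correlated; age correlates with disease duration)."""
    s = config._covariate_settings()
    names = ["age_years", "disease_duration_years", "tjc28", "sjc28",
             "esr_mm_hr", "patient_global_0_100", "haq_0_3"]
    # default copula correlation: disease-activity cluster ~0.3-0.45
    R = np.eye(7)
    pairs = {(0, 1): 0.35, (2, 3): 0.45, (2, 5): 0.35, (3, 5): 0.30,
             (2, 6): 0.30, (3, 6): 0.25, (5, 6): 0.35, (4, 2): 0.15,
             (4, 3): 0.15, (4, 6): 0.10}
    for (i, j), r in pairs.items():
        R[i, j] = R[j, i] = r
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, 7)) @ L.T

    df = pd.DataFrame(index=np.arange(n))
    df["age_years"] = np.clip(s["age_years"][0] + s["age_years"][1] * z[:, 0], 18, 92).round(1)
    df["disease_duration_years"] = np.clip(
        np.exp(s["disease_duration_years"][0] + s["disease_duration_years"][1] * z[:, 1]),
        0.5, 55).round(1)
    df["tjc28"] = np.clip(np.exp(s["tjc28"][0] + s["tjc28"][1] * z[:, 2]), 0, 28).round()
    df["sjc28"] = np.clip(np.exp(s["sjc28"][0] + s["sjc28"][1] * z[:, 3]), 0, 28).round()
    df["esr_mm_hr"] = np.clip(np.exp(s["esr_mm_hr"][0] + s["esr_mm_hr"][1] * z[:, 4]), 2, 140).round(1)
    df["patient_global_0_100"] = np.clip(
        s["patient_global_0_100"][0] + s["patient_global_0_100"][1] * z[:, 5], 0, 100).round()
    df["haq_0_3"] = (np.clip(s["haq_0_3"][0] + s["haq_0_3"][1] * z[:, 6], 0, 3) * 8).round() / 8

    df["das28"] = das28_composite(df["tjc28"], df["sjc28"], df["esr_mm_hr"],
                                  df["patient_global_0_100"])
    df["female"] = (rng.random(n) < 0.80).astype(int)
    df["rheumatoid_factor_flag"] = (rng.random(n) < 0.67).astype(int)
    df["comorbidity_flag"] = (rng.random(n) < 0.645).astype(int)
    df["n_previous_dmards"] = np.clip(1 + rng.poisson(2.0, n), 1, 8)
    df["n_previous_biologics"] = 1 + (rng.random(n) < 0.08).astype(int)
    df["stop_reason_inefficacy_flag"] = (rng.random(n) < 0.50).astype(int)
    df["glucocorticoid_flag"] = (rng.random(n) < 0.46).astype(int)
    doses = np.array([5, 7.5, 10, 12.5, 15, 17.5, 20, 25])
    probs = np.array([0.10, 0.15, 0.30, 0.15, 0.15, 0.06, 0.06, 0.03])
    df["mtx_weekly_dose_mg"] = rng.choice(doses, size=n, p=probs / probs.sum())
    return df


# standardisation constants for the structural (assignment / outcome)
# linear predictors; fixed so that coefficients are comparable across runs
_STD_SCALE = {
    "age_years": (60.0, 11.0),
    "disease_duration_years": (16.0, 10.0),
    "tjc28": (10.0, 7.0),
    "sjc28": (6.5, 5.0),
    "esr_mm_hr": (40.0, 28.0),
    "patient_global_0_100": (63.0, 22.0),
    "das28": (5.5, 1.0),
    "haq_0_3": (1.9, 0.55),
    "mtx_weekly_dose_mg": (11.0, 4.5),
    "n_previous_dmards": (3.0, 1.4),
}


def _linear_predictor(df: pd.DataFrame, coefficients: dict) -> np.ndarray:
    eta = np.full(len(df), float(coefficients.get("intercept", 0.0)))
    for name, coef in coefficients.items():
        if name == "intercept":
            continue
        x = df[name].to_numpy(dtype=float)
        if name in _STD_SCALE:
            x = _standardize(x, *_STD_SCALE[name])
        eta = eta + coef * x
    return eta


def _po_project(q0: np.ndarray, q1: np.ndarray) -> tuple:
    """KL projection of two three-category distributions onto the
    proportional-odds family with equal arm weights; returns
    (alpha1, alpha2, beta) of the fitted model."""

    def nll(theta):
        c1, c2, b = theta
        out = 0.0
        for t, q in ((0.0, q0), (1.0, q1)):
            s1, s2 = expit(c1 + b * t), expit(c2 + b * t)
            p = np.clip([1 - s1, s1 - s2, s2], 1e-12, 1.0)
            out -= float(q @ np.log(p))
        return out

    start = np.array([logit(np.clip(q0[1] + q0[2], 1e-6, 1 - 1e-6)),
                      logit(np.clip(q0[2], 1e-6, 1 - 1e-6)), 0.0])
    res = minimize(nll, start, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return tuple(res.x)


def calibrate_outcome_model(config: SyntheticConfig) -> dict:
    """Solve for conditional outcome-model parameters.

    Returns a dict with cutpoints ``alpha1``/``alpha2`` (chosen so the
    marginal control probabilities over the eligible population equal
    ``control_response_targets``) and the conditional treatment effect
    ``beta_conditional`` (chosen so the marginal proportional-odds
    projection of the treated-vs-control category distributions has log
    odds ratio ``true_log_or``).  Cached per configuration.
    """
    key = (json.dumps(config.prognostic_coefficients, sort_keys=True),
           tuple(config.control_response_targets), float(config.true_log_or),
           json.dumps(config.covariate_generators, sort_keys=True, default=str))
    if key in _calibration_cache:
        return _calibration_cache[key]

    rng = np.random.default_rng(_CALIBRATION_SAMPLE_SEED)
    cov = _draw_covariates(config, rng, _CALIBRATION_SAMPLE_SIZE)
    cov = cov[cov["das28"] > 3.2]
    eta = _linear_predictor(cov, config.prognostic_coefficients)

    p_mod, p_good = config.control_response_targets

    def mean_prob(alpha):
        return float(np.mean(expit(alpha + eta)))

    alpha1 = brentq(lambda a: mean_prob(a) - p_mod, -15, 15, xtol=1e-10)
    alpha2 = brentq(lambda a: mean_prob(a) - p_good, -15, 15, xtol=1e-10)

    def marginal_categories(beta_c, treated):
        shift = beta_c if treated else 0.0
        s1 = np.mean(expit(alpha1 + eta + shift))
        s2 = np.mean(expit(alpha2 + eta + shift))
        return np.array([1 - s1, s1 - s2, s2])

    q0 = marginal_categories(0.0, False)

    def fitted_beta(beta_c):
        q1 = marginal_categories(beta_c, True)
        return _po_project(q0, q1)[2]

    target = float(config.true_log_or)
    if abs(target) < 1e-12:
        beta_c = 0.0
    else:
        hi = 3.0 * target if target > 0 else 3.0 * target
        beta_c = brentq(lambda b: fitted_beta(b) - target,
                        min(0.0, hi), max(0.0, hi), xtol=1e-8)

    out = {"alpha1": float(alpha1), "alpha2": float(alpha2),
           "beta_conditional": float(beta_c)}
    _calibration_cache[key] = out
    return out


# ---------------------------------------------------------------------------
# outcome generation
# ---------------------------------------------------------------------------

def _draw_categories(rng, alpha1, alpha2, eta, beta_c, treated) -> np.ndarray:
    shift = beta_c * treated
    s1 = expit(alpha1 + eta + shift)   # P(Y >= moderate)
    s2 = expit(alpha2 + eta + shift)   # P(Y >= good) = P(good)
    u = rng.random(len(eta))
    # cumulative from the top: u < s2 -> good; u < s1 -> moderate
    cat = np.zeros(len(eta), dtype=np.int64)
    cat[u < s1] = 1
    cat[u < s2] = 2
    return cat


def _category_interval(b: np.ndarray, cat: np.ndarray):
    """Follow-up DAS28 interval consistent with category ``cat`` at
    baseline ``b``.  Each EULAR category corresponds to a single interval
    of follow-up values (see the criteria grid); returns (lo, hi)."""
    f1 = b - 1.2   # improvement > 1.2  <=>  f < f1
    f2 = b - 0.6   # improvement > 0.6  <=>  f < f2
    lo = np.empty_like(b)
    hi = np.empty_like(b)
    good = cat == 2
    mod = cat == 1
    none = cat == 0
    lo[good] = 0.0
    hi[good] = np.minimum(3.2, f1[good])
    lo[mod] = np.clip(np.minimum(f1[mod], 3.2), 0.0, None)
    hi[mod] = np.maximum(f1[mod], np.minimum(f2[mod], 5.1))
    lo[none] = np.where(f2[none] > 5.1, np.maximum(f1[none], 5.1), f2[none])
    lo[none] = np.clip(lo[none], 0.0, None)
    hi[none] = 10.0
    return lo, hi


def _sample_followup_das28(rng, baseline, cat):
    """Back-solve a follow-up DAS28 uniformly from the region consistent
    with the drawn category.  For baselines where the drawn category is
    infeasible (only possible at DAS28 <= 3.2, i.e. outside the eligible
    range) the category is downgraded to the best feasible one."""
    b = np.asarray(baseline, dtype=float)
    cat = np.asarray(cat).copy()
    for _ in range(2):
        lo, hi = _category_interval(b, cat)
        empty = hi <= lo
        if not empty.any():
            break
        cat[empty] = cat[empty] - 1
    lo, hi = _category_interval(b, cat)
    # shrink marginally away from the boundary so classification is
    # unambiguous under floating point
    eps = 1e-9
    f = lo + (hi - lo) * rng.uniform(eps, 1 - eps, size=len(b))
    return f, cat


def _components_for_das28(rng, das28_target):
    """Pick plausible DAS28 components that reproduce ``das28_target``
    exactly: joint counts and patient global are set near their expected
    share of the composite, then ESR absorbs the residual."""
    d = np.asarray(das28_target, dtype=float)
    n = len(d)
    tjc = np.clip(np.round((0.30 * d / 0.56) ** 2 + rng.normal(0, 1.0, n)), 0, 28)
    sjc = np.clip(np.round((0.12 * d / 0.28) ** 2 + rng.normal(0, 0.8, n)), 0, 28)
    pga = np.clip(np.round(10.7 * d + rng.normal(0, 8.0, n)), 0, 100)
    resid = d - 0.56 * np.sqrt(tjc) - 0.28 * np.sqrt(sjc) - 0.014 * pga
    esr = np.exp(resid / 0.70)
    return tjc, sjc, esr, pga


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

FOLLOWUP_DAYS = 168          # 24 weeks
_OBS_TAIL_DAYS = 400         # observation continues past follow-up
_MEAS_WINDOW_DAYS = 100      # protective radius around measurement visits


def generate_cohort(config: SyntheticConfig) -> RegistryCohort:
    """Generate a complete registry cohort (no missingness).

    The same (config, seed) always reproduces the cohort bit-identically.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    patients = _draw_covariates(config, rng, n)
    patients.insert(0, "patient_id", np.arange(1, n + 1))

    # --- confounded treatment assignment -------------------------------
    e = expit(_linear_predictor(patients, config.assignment_coefficients))
    treated = (rng.random(n) < e).astype(int)

    # --- ordinal outcome under the calibrated proportional-odds model --
    cal = calibrate_outcome_model(config)
    eta_out = _linear_predictor(patients, config.prognostic_coefficients)
    cat = _draw_categories(rng, cal["alpha1"], cal["alpha2"], eta_out,
                           cal["beta_conditional"], treated)
    das28_baseline = patients["das28"].to_numpy()
    das28_followup, cat = _sample_followup_das28(rng, das28_baseline, cat)

    # --- episode skeleton ----------------------------------------------
    registration = np.zeros(n)  # days since epoch, per patient
    fl_start = registration + rng.uniform(0, 30, n)
    fl_duration = np.clip(rng.lognormal(np.log(650), 0.5, n), 90, 2500)
    fl_stop = fl_start + fl_duration

    drugs = np.array(["ADA", "ETN", "IFX", "TCZ", "ABT", "CTZ", "GOL"])
    drug_p = np.array([0.32, 0.31, 0.255, 0.04, 0.02, 0.035, 0.02])
    prior_drug = rng.choice(drugs, size=n, p=drug_p / drug_p.sum())
    prior_is_rtx = rng.random(n) < config.prior_rtx_rate
    prior_drug = np.where(prior_is_rtx, "RTX", prior_drug)

    stop_reason = np.where(
        patients["stop_reason_inefficacy_flag"].to_numpy() == 1, "inefficacy",
        np.where(rng.random(n) < 0.5, "adverse_event", "other"))

    # candidate baseline per assigned strategy
    rtx_gap = rng.uniform(*config.rtx_gap_days, n)
    baseline = np.where(treated == 1, fl_stop + rtx_gap, fl_stop)
    followup = baseline + FOLLOWUP_DAYS
    obs_end = followup + _OBS_TAIL_DAYS

    episode_rows = []

    def add_episodes(mask, drug, start, stop, reason=None):
        ids = patients.loc[mask, "patient_id"].to_numpy()
        episode_rows.append(pd.DataFrame({
            "patient_id": ids,
            "drug_label": drug if isinstance(drug, str) else drug[mask],
            "start_day": np.asarray(start)[mask] if np.ndim(start) else np.full(mask.sum(), start),
            "stop_day": np.asarray(stop)[mask] if stop is not None else np.full(mask.sum(), np.nan),
            "stop_reason": (np.asarray(reason)[mask] if np.ndim(reason)
                            else np.full(mask.sum(), reason if reason else "")),
        }))

    all_mask = np.ones(n, dtype=bool)
    # methotrexate backbone
    on_mtx = rng.random(n) < config.mtx_coverage
    mtx_stop = np.where(on_mtx, np.nan,
                        np.clip(baseline - rng.uniform(30, 200, n), 5, None))
    add_episodes(all_mask, "MTX", registration, mtx_stop, "")
    # failed first-line biologic
    add_episodes(all_mask, prior_drug, fl_start, fl_stop, stop_reason)

    # second-line rituximab course
    is_rtx_arm = treated == 1
    rtx_disc = is_rtx_arm & (rng.random(n) < config.rtx_discontinue_rate)
    rtx_stop = np.where(rtx_disc, baseline + rng.uniform(30, 160, n), np.nan)
    rtx_reason = np.where(rtx_disc,
                          np.where(rng.random(n) < 0.6, "inefficacy", "adverse_event"),
                          "")
    add_episodes(is_rtx_arm, "RTX", baseline, rtx_stop, rtx_reason)

    # nonbiologic arm: a configurable fraction starts another biologic
    is_nbt = treated == 0
    u_nbt = rng.random(n)
    early = is_nbt & (u_nbt < config.nbt_early_biologic_rate)
    mid = is_nbt & ~early & (u_nbt < config.nbt_early_biologic_rate
                             + config.nbt_mid_biologic_rate)
    late = is_nbt & ~early & ~mid & (u_nbt < config.nbt_early_biologic_rate
                                     + config.nbt_mid_biologic_rate
                                     + config.nbt_late_rtx_rate)
    next_drug = rng.choice(np.array(["ADA", "ETN", "IFX"]), size=n)
    early_start = fl_stop + rng.uniform(7, 133, n)      # < 20 weeks
    mid_start = fl_stop + rng.uniform(140, 167, n)      # weeks 20-24
    late_start = fl_stop + rng.uniform(200, 320, n)     # after follow-up
    add_episodes(early, next_drug, early_start, None, "")
    add_episodes(mid, next_drug, mid_start, None, "")
    add_episodes(late, "RTX", late_start, None, "")

    episodes = pd.concat(episode_rows, ignore_index=True)
    episodes = episodes.sort_values(["patient_id", "start_day", "drug_label"],
                                    kind="stable").reset_index(drop=True)

    # --- visit schedule -------------------------------------------------
    max_window = float(np.max(obs_end))
    n_slots = int(np.ceil(max_window / max(
        config.visit_interval_days - 2 * config.visit_jitter_days, 30))) + 2
    gaps = rng.normal(config.visit_interval_days, config.visit_jitter_days,
                      (n, n_slots))
    gaps = np.clip(gaps, 60, None)
    grid = np.cumsum(gaps, axis=1) - gaps[:, [0]]  # first visit at registration

    jb = np.clip(rng.normal(0, config.measurement_jitter_days, n), -45, 45)
    jf = np.clip(rng.normal(0, config.measurement_jitter_days, n), -45, 45)
    meas_baseline_day = baseline + jb
    meas_followup_day = followup + jf
    missed = rng.random(n) < config.missing_followup_rate

    keep = (grid <= obs_end[:, None])
    keep &= np.abs(grid - meas_baseline_day[:, None]) > _MEAS_WINDOW_DAYS
    keep &= np.abs(grid - meas_followup_day[:, None]) > _MEAS_WINDOW_DAYS
    # a missed 6-month assessment: no visit near the follow-up date at all
    keep &= ~(missed[:, None] & (np.abs(grid - followup[:, None]) <= _MEAS_WINDOW_DAYS))

    pid_grid = np.repeat(patients["patient_id"].to_numpy(), n_slots)
    day_grid = grid.ravel()
    keep_flat = keep.ravel()

    # DAS28 trajectory at routine visits: near baseline level before the
    # treatment switch, near the follow-up level afterwards
    base_rep = np.repeat(das28_baseline, n_slots)
    fup_rep = np.repeat(das28_followup, n_slots)
    switch_rep = np.repeat(baseline, n_slots)
    traj = np.where(day_grid <= switch_rep, base_rep, fup_rep)
    traj = np.clip(traj + rng.normal(0, 0.4, traj.shape), 0.3, 9.7)

    grid_visits = pd.DataFrame({
        "patient_id": pid_grid[keep_flat],
        "visit_day": day_grid[keep_flat],
        "das28_target": traj[keep_flat],
        "is_measurement": 0,
    })

    meas_b = pd.DataFrame({
        "patient_id": patients["patient_id"],
        "visit_day": meas_baseline_day,
        "das28_target": das28_baseline,
        "is_measurement": 1,
    })
    meas_f = pd.DataFrame({
        "patient_id": patients["patient_id"][~missed],
        "visit_day": meas_followup_day[~missed],
        "das28_target": das28_followup[~missed],
        "is_measurement": 1,
    })

    visits = pd.concat([grid_visits, meas_b, meas_f], ignore_index=True)
    visits = visits.sort_values(["patient_id", "visit_day"],
                                kind="stable").reset_index(drop=True)

    # components: baseline measurement visits reuse the patient's actual
    # baseline components; everything else is back-solved from the target
    vr = np.random.default_rng(rng.integers(2 ** 31))
    tjc, sjc, esr, pga = _components_for_das28(vr, visits["das28_target"].to_numpy())
    is_mb = visits.merge(meas_b.assign(_mb=1)[["patient_id", "visit_day", "_mb"]],
                         on=["patient_id", "visit_day"], how="left")["_mb"].fillna(0).to_numpy()
    pat_idx = visits["patient_id"].to_numpy() - 1
    for arr, col in ((tjc, "tjc28"), (sjc, "sjc28"), (esr, "esr_mm_hr"),
                     (pga, "patient_global_0_100")):
        arr[is_mb == 1] = patients[col].to_numpy()[pat_idx[is_mb == 1]]
    visits["tjc28"] = tjc.astype(int)
    visits["sjc28"] = sjc.astype(int)
    visits["esr_mm_hr"] = esr
    visits["patient_global_0_100"] = pga
    visits["das28"] = das28_composite(tjc, sjc, esr, pga)
    visits["haq_0_3"] = np.clip(
        patients["haq_0_3"].to_numpy()[pat_idx] + vr.normal(0, 0.15, len(visits)), 0, 3)
    visits = visits.drop(columns=["das28_target", "is_measurement"])
    visits["date"] = _EPOCH + pd.to_timedelta(np.round(visits["visit_day"]).astype(int), unit="D")
    visits = visits.drop(columns=["visit_day"])
    visits = visits[["patient_id", "date", "tjc28", "sjc28", "esr_mm_hr",
                     "patient_global_0_100", "das28", "haq_0_3"]]
    visits = visits.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)

    # --- finalize tables -------------------------------------------------
    patients["previous_biologic"] = prior_drug
    patients["registration_date"] = _EPOCH
    patients["observation_end_date"] = _EPOCH + pd.to_timedelta(
        np.ceil(obs_end).astype(int), unit="D")
    patients = patients[["patient_id", "registration_date", "observation_end_date",
                         "previous_biologic"] + COVARIATE_COLUMNS]

    for col in ("start_day", "stop_day"):
        episodes[col.replace("_day", "_date")] = _EPOCH + pd.to_timedelta(
            np.floor(episodes[col].to_numpy(dtype=float)), unit="D")
    episodes = episodes[["patient_id", "drug_label", "start_date", "stop_date",
                         "stop_reason"]]

    truth = pd.DataFrame({
        "patient_id": patients["patient_id"],
        "treated": treated,
        "eular_category": cat,
        "das28_baseline": das28_baseline,
        "das28_followup": das28_followup,
        "propensity_true": e,
        "baseline_day": baseline,
        "followup_day": followup,
        "missed_followup_visit": missed.astype(int),
        "rtx_discontinued": rtx_disc.astype(int),
        "nbt_early_biologic": early.astype(int),
        "nbt_mid_biologic": mid.astype(int),
    })

    meta = {"seed": config.seed, "n_patients": n,
            "true_log_or": config.true_log_or,
            "outcome_model": cal,
            "missingness": {"mechanism": "none"}}
    return RegistryCohort(patients, visits, episodes, truth, meta)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def inject_missingness(cohort: RegistryCohort,
                       config: SyntheticConfig) -> RegistryCohort:
    """Mask baseline covariates missing-at-random.

    Rates come from ``config.missingness_rates``: either a scalar
    probability per covariate, or a length-3 sequence of probabilities
    applied by baseline-DAS28 tertile (a missing-at-random mechanism
    keyed on an always-observed covariate).  The realised mechanism is
    recorded in ``cohort.meta['missingness']`` for test introspection.
    """
    config.validate()
    out = cohort.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7241]))
    das28 = out.patients["das28"].to_numpy()
    tertile = np.searchsorted(np.quantile(das28, [1 / 3, 2 / 3]), das28)

    mechanism = {}
    for col, rate in config.missingness_rates.items():
        if col not in out.patients.columns:
            raise ConfigurationError(f"unknown covariate {col!r} in missingness_rates")
        rates = np.atleast_1d(np.asarray(rate, dtype=float))
        if rates.size == 1:
            p = np.full(len(das28), rates[0])
            mechanism[col] = {"type": "MCAR", "rate": float(rates[0])}
        elif rates.size == 3:
            p = rates[tertile]
            mechanism[col] = {"type": "MAR_das28_tertile",
                              "rates": rates.tolist()}
        else:
            raise ConfigurationError(
                f"rate for {col!r} must be a scalar or a DAS28-tertile triple")
        mask = rng.random(len(das28)) < p
        vals = out.patients[col].astype(float).to_numpy()
        vals[mask] = np.nan
        out.patients[col] = vals
    out.meta = dict(out.meta)
    out.meta["missingness"] = {"mechanism": mechanism,
                               "conditioning": "das28_tertile"}
    return out


# ---------------------------------------------------------------------------
# persistence (delimited-text schema)
# ---------------------------------------------------------------------------

_TABLES = ("patients", "visits", "episodes")


def write_registry(cohort: RegistryCohort, path) -> None:
    """Write a cohort to ``path`` as patients.csv / visits.csv /
    episodes.csv (plus truth.csv and meta.json when available)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(path / "patients.csv", index=False)
    cohort.visits.to_csv(path / "visits.csv", index=False)
    cohort.episodes.to_csv(path / "episodes.csv", index=False)
    if cohort.truth is not None:
        cohort.truth.to_csv(path / "truth.csv", index=False)
    (path / "meta.json").write_text(json.dumps(cohort.meta, indent=2, default=str))


def read_registry(path) -> RegistryCohort:
    """Read and validate a cohort directory written by write_registry."""
    path = Path(path)
    for t in _TABLES:
        if not (path / f"{t}.csv").exists():
            raise RegistryValidationError(f"missing table {t}.csv in {path}")
    patients = pd.read_csv(path / "patients.csv",
                           parse_dates=["registration_date", "observation_end_date"])
    visits = pd.read_csv(path / "visits.csv", parse_dates=["date"])
    episodes = pd.read_csv(path / "episodes.csv",
                           parse_dates=["start_date", "stop_date"])
    episodes["stop_reason"] = episodes["stop_reason"].fillna("")
    truth = None
    if (path / "truth.csv").exists():
        truth = pd.read_csv(path / "truth.csv")
    meta = {}
    if (path / "meta.json").exists():
        meta = json.loads((path / "meta.json").read_text())
    _validate_tables(patients, visits, episodes)
    return RegistryCohort(patients, visits, episodes, truth, meta)


def _validate_tables(patients, visits, episodes) -> None:
    required = {"patients": ["patient_id", "registration_date",
                             "observation_end_date"] + COVARIATE_COLUMNS,
                "visits": ["patient_id", "date", "tjc28", "sjc28", "esr_mm_hr",
                           "patient_global_0_100", "das28", "haq_0_3"],
                "episodes": ["patient_id", "drug_label", "start_date",
                             "stop_date", "stop_reason"]}
    for name, df in (("patients", patients), ("visits", visits),
                     ("episodes", episodes)):
        missing = [c for c in required[name] if c not in df.columns]
        if missing:
            raise RegistryValidationError(
                f"table {name!r} lacks required columns {missing}")
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise RegistryValidationError(f"duplicate patient_id {dup} in patients table")

    known = set(patients["patient_id"])
    for name, df in (("visits", visits), ("episodes", episodes)):
        if len(df):
            stray = set(df["patient_id"]) - known
            if stray:
                raise RegistryValidationError(
                    f"table {name!r} references unknown patient_id {sorted(stray)[:3]}")

    if len(visits):
        ordered = visits.groupby("patient_id")["date"].is_monotonic_increasing
        if not ordered.all():
            bad = ordered[~ordered].index[0]
            raise RegistryValidationError(
                f"visits for patient {bad} are not ordered by date")

    if len(episodes):
        stopped = episodes.dropna(subset=["stop_date"])
        bad = stopped[stopped["stop_date"] < stopped["start_date"]]
        if len(bad):
            r = bad.iloc[0]
            raise RegistryValidationError(
                f"episode for patient {r['patient_id']} ({r['drug_label']}) "
                f"stops before it starts")
        # episodes of the same drug must not overlap (concurrent
        # methotrexate alongside a biologic is legitimate, so the
        # non-overlap rule applies within drug label)
        e = episodes.sort_values(["patient_id", "drug_label", "start_date"])
        same = (e["patient_id"].eq(e["patient_id"].shift())
                & e["drug_label"].eq(e["drug_label"].shift()))
        prev_stop = e["stop_date"].shift()
        overlap = same & (prev_stop.isna() | (e["start_date"] < prev_stop))
        if overlap.any():
            r = e[overlap].iloc[0]
            raise RegistryValidationError(
                f"overlapping {r['drug_label']} episodes for patient "
                f"{r['patient_id']}")
        # every episode lies inside the patient's observation window
        w = episodes.merge(patients[["patient_id", "registration_date",
                                     "observation_end_date"]], on="patient_id")
        out_of_window = ((w["start_date"] < w["registration_date"])
                         | (w["start_date"] > w["observation_end_date"])
                         | (w["stop_date"].notna()
                            & (w["stop_date"] > w["observation_end_date"])))
        if out_of_window.any():
            r = w[out_of_window].iloc[0]
            raise RegistryValidationError(
                f"episode for patient {r['patient_id']} ({r['drug_label']}) "
                f"falls outside the observation window")
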