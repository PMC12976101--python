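"""Discrete-event simulation: closed forms, conservation, coupling and
acceptability-curve properties."""

import math

import numpy as np
import pandas as pd
import pytest

from ttehta.economic_model import (EconConfig, Strategy, TreatmentParams,
                                   audit_trace, average_biologic, ceac,
                                   compute_icer, default_biologic_strategy,
                                   default_nbt_strategy, run_cohort, run_psa,
                                   simulate_individual)
from ttehta.economic_model import _individual_uniforms, _utility
from ttehta.evidence_synthesis import ResponseProbabilityInputs


def _still_config(**kw):
    base = dict(horizon_years=10.0, discount_rate_costs=0.0,
                discount_rate_qalys=0.0, haq_progression_nbt=0.0,
                mortality_baseline_hazard=0.0, baseline_haq_mean=1.0,
                baseline_haq_sd=0.0)
    base.update(kw)
    return EconConfig(**base)


def test_undiscounted_immortal_run_matches_closed_form():
    """No mortality, no discounting, a single never-stopped treatment:
    QALY = u * T exactly and cost = per-period cost * number of periods."""
    cfg = _still_config()
    strat = default_nbt_strategy()
    u = _individual_uniforms(1, 0, cfg)
    cost, qaly, trace = simulate_individual(u, strat, cfg, record_trace=True)
    util = _utility(1.0, cfg)
    assert qaly == pytest.approx(util * 10.0, abs=1e-9)
    assert cost == pytest.approx(250.0 * 20, abs=1e-9)
    audit = audit_trace(trace)
    assert audit["cost"] == pytest.approx(cost, abs=1e-9)
    assert audit["qaly"] == pytest.approx(qaly, abs=1e-9)


def test_discounted_run_matches_annuity_closed_form():
    cfg = _still_config(discount_rate_costs=0.035, discount_rate_qalys=0.035)
    strat = default_nbt_strategy()
    u = _individual_uniforms(1, 0, cfg)
    cost, qaly, _ = simulate_individual(u, strat, cfg)
    delta = math.log1p(0.035)
    util = _utility(1.0, cfg)
    annuity = util * (1 - math.exp(-delta * 10.0)) / delta
    assert qaly == pytest.approx(annuity, abs=1e-9)
    expected_cost = 250.0 * sum(math.exp(-delta * 0.5 * k) for k in range(20))
    assert cost == pytest.approx(expected_cost, abs=1e-9)


def test_certain_nonresponse_switches_at_exactly_six_months():
    cfg = _still_config()
    first = TreatmentParams("biologic", (1.0, 0.0, 0.0))
    strat = Strategy("bio", [first, default_nbt_strategy().treatments[0]])
    u = _individual_uniforms(2, 0, cfg)
    cost, qaly, trace = simulate_individual(u, strat, cfg, record_trace=True)
    switches = [e for e in trace if e["event"] == "assessment:biologic"]
    assert len(switches) == 1
    assert switches[0]["time"] == pytest.approx(0.5)
    assert switches[0]["category"] == "none"
    # exactly one six-month period of the first drug was charged
    charged = [e for e in trace if e["event"] == "cost:biologic"]
    assert len(charged) == 1


def test_trace_cost_conservation_under_mortality_and_discounting():
    cfg = EconConfig(horizon_years=40, seed=0)
    strat = default_biologic_strategy()
    for i in range(50):
        u = _individual_uniforms(3, i, cfg)
        cost, qaly, trace = simulate_individual(u, strat, cfg, record_trace=True)
        audit = audit_trace(trace)
        assert audit["cost"] == pytest.approx(cost, abs=1e-9)
        assert audit["qaly"] == pytest.approx(qaly, abs=1e-9)
        assert np.isfinite(cost) and np.isfinite(qaly)


def test_identical_strategies_with_crn_are_identical():
    cfg = EconConfig(n_individuals=100, seed=4)
    a = run_cohort(default_biologic_strategy(), cfg, seed=9)
    b = run_cohort(default_biologic_strategy(), cfg, seed=9)
    assert a["mean_cost"] == b["mean_cost"]
    assert a["mean_qaly"] == b["mean_qaly"]


def test_monte_carlo_error_shrinks_with_cohort_size():
    cfg = EconConfig(seed=5)
    small = run_cohort(default_nbt_strategy(), cfg, n_individuals=400)
    large = run_cohort(default_nbt_strategy(), cfg, n_individuals=1600)
    ratio = small["se_qaly"] / large["se_qaly"]
    assert ratio == pytest.approx(2.0, rel=0.35)


def test_better_response_probabilities_never_reduce_qalys():
    """Monotone coupling: raising the good-response probability with
    common random numbers cannot lower the strategy's mean QALY."""
    cfg = EconConfig(n_individuals=300, seed=6)
    worse = default_biologic_strategy(rtx_response=(0.50, 0.40, 0.10))
    better = default_biologic_strategy(rtx_response=(0.20, 0.40, 0.40))
    qw = run_cohort(worse, cfg, seed=8)["mean_qaly"]
    qb = run_cohort(better, cfg, seed=8)["mean_qaly"]
    assert qb >= qw


def test_icer_arithmetic_and_quadrants():
    assert compute_icer(20000.0, 0.5)["icer"] == pytest.approx(40000.0)
    assert compute_icer(20000.0, 0.5)["quadrant"] == "NE"
    assert compute_icer(-1.0, 1.0)["quadrant"] == "SE"   # dominant
    with pytest.raises(ValueError, match="undefined"):
        compute_icer(100.0, 0.0)


def test_average_biologic_pooling():
    r = [{"mean_cost": 10.0, "mean_qaly": 5.0},
         {"mean_cost": 20.0, "mean_qaly": 6.0}]
    avg = average_biologic(r)
    assert avg["mean_qaly"] == pytest.approx(5.5)
    rev = average_biologic(r[::-1])
    assert rev == avg | {"strategy": "biologic-average"}
    single = average_biologic(r[:1])
    assert single["mean_cost"] == 10.0


def test_degenerate_psa_collapses_to_deterministic_run():
    """Point-mass inputs with structural sampling off: every iteration
    is identical and equals the single deterministic cohort run."""
    cfg = EconConfig(n_individuals=150, seed=7)
    point = ResponseProbabilityInputs.from_probabilities(0.45, 0.15)
    psa = run_psa(point, cfg, n_iterations=5, n_individuals=150,
                  sample_structural=False)
    it = psa.iterations
    assert it["delta_cost"].nunique() == 1
    assert it["delta_qaly"].nunique() == 1

    bio = default_biologic_strategy(tuple(point.draws[0]))
    nbt = default_nbt_strategy()
    det_b = run_cohort(bio, cfg, seed=cfg.seed, n_individuals=150)
    det_n = run_cohort(nbt, cfg, seed=cfg.seed, n_individuals=150)
    assert it["delta_cost"].iloc[0] == pytest.approx(
        det_b["mean_cost"] - det_n["mean_cost"], abs=1e-9)
    assert it["delta_qaly"].iloc[0] == pytest.approx(
        det_b["mean_qaly"] - det_n["mean_qaly"], abs=1e-9)


def test_psa_is_reproducible():
    cfg = EconConfig(n_individuals=80, seed=12)
    point = ResponseProbabilityInputs.from_probabilities(0.5, 0.2)
    a = run_psa(point, cfg, n_iterations=4, n_individuals=80)
    b = run_psa(point, cfg, n_iterations=4, n_individuals=80)
    pd.testing.assert_frame_equal(a.iterations, b.iterations)


def test_ceac_definition_and_step_shape():
    it = pd.DataFrame({"delta_cost": [20000.0] * 4, "delta_qaly": [0.5] * 4,
                       "icer": [40000.0] * 4})
    from ttehta.economic_model import PSAResult
    psa = PSAResult(it, ("a", "b"), 100, 0)
    curve = ceac(psa, np.array([0.0, 30000.0, 40000.0, 50000.0, 80000.0]))
    # step from 0 to 1 at the common ICER; at lambda=0 the probability is
    # the fraction of cost-saving iterations
    assert curve["probability_cost_effective"].tolist() == [0.0, 0.0, 0.0, 1.0, 1.0]


def test_ceac_monotone_when_all_gains_positive():
    cfg = EconConfig(n_individuals=100, seed=13)
    point = ResponseProbabilityInputs.from_probabilities(0.5, 0.2)
    psa = run_psa(point, cfg, n_iterations=10, n_individuals=100)
    assert (psa.iterations["delta_qaly"] > 0).all()
    curve = ceac(psa, np.arange(0, 100001, 5000, dtype=float))
    assert (np.diff(curve["probability_cost_effective"]) >= 0).all()


def test_strategy_validation():
    with pytest.raises(ValueError, match="non-empty"):
        Strategy("empty", []).validate()
    with pytest.raises(ValueError, match="terminal"):
        Strategy("open", [TreatmentParams("a")]).validate()
    with pytest.raises(ValueError, match="summing"):
        TreatmentParams("bad", (0.5, 0.2, 0.2)).validate()


def test_plots_are_written(tmp_path):
    from ttehta.economic_model import ce_plane_plot, ceac_plot
    cfg = EconConfig(n_individuals=50, seed=14)
    point = ResponseProbabilityInputs.from_probabilities(0.5, 0.2)
    psa = run_psa(point, cfg, n_iterations=3, n_individuals=50)
    ce_plane_plot({"demo": psa}, tmp_path / "plane.svg")
    ceac_plot({"demo": ceac(psa)}, tmp_path / "ceac.svg")
    assert (tmp_path / "plane.svg").stat().st_size > 0
    assert (tmp_path / "ceac.svg").stat().st_size > 0
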