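"""Discrete-event cost-effectiveness model for biologic treatment sequences.

A reconstructed, deliberately simplified sequence model for rheumatoid
arthritis: each simulated individual moves through an ordered treatment
sequence (first-line biologic, then rituximab, then nonbiologic therapy
as the absorbing final line).  Six months after starting a treatment the
EULAR response is assessed; nonresponders switch to the next line
immediately, responders gain a category-specific HAQ improvement and
remain on treatment for a sampled time-on-treatment, after which HAQ
rebounds to its pre-treatment level and the next line starts.  On
nonbiologic therapy HAQ progresses at a constant rate, bounded in
[0, 3].  Utility is a clamped linear function of HAQ; mortality follows
a constant baseline hazard multiplied by a hazard ratio per HAQ point;
costs accrue per six-month treatment period.  Costs and utilities are
discounted continuously at ln(1 + annual rate).

All structural parameters (costs, HAQ effects, time-on-treatment means,
utility mapping, mortality) are configurable illustrative defaults: the
absolute cost and QALY magnitudes produced here are not calibrated to
any published health-technology appraisal, and only directions of
effect and internal consistency are meaningful.

Simulation draws are synchronised across strategies through common
random numbers: each individual owns a fixed pool of uniforms (one per
decision slot) and a single cumulative-hazard threshold for death, so
that improving a treatment's response distribution can only postpone
events in one direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentParams",
    "Strategy",
    "EconConfig",
    "PSAResult",
    "default_biologic_strategy",
    "default_nbt_strategy",
    "simulate_individual",
    "audit_trace",
    "run_cohort",
    "average_biologic",
    "run_psa",
    "compute_icer",
    "ceac",
    "ce_plane_plot",
    "ceac_plot",
]

ASSESSMENT_YEARS = 0.5
PERIOD_YEARS = 0.5
CATEGORY_LABELS = ("none", "moderate", "good")


@dataclass
class TreatmentParams:
    """Parameters of one treatment line.

    ``response_probs`` are the (none, moderate, good) EULAR probabilities
    at the six-month assessment.  ``is_terminal`` marks the absorbing
    final line (nonbiologic therapy): no assessment-driven switching,
    and HAQ progresses at the configured rate.
    """

    name: str
    response_probs: tuple = (0.4, 0.4, 0.2)
    haq_change: dict = field(default_factory=lambda: {
        "none": 0.0, "moderate": -0.32, "good": -0.55})
    tot_mean_years: dict = field(default_factory=lambda: {
        "moderate": 2.0, "good": 3.5})
    cost_6mo_drug: float = 4600.0
    cost_6mo_admin: float = 300.0
    is_terminal: bool = False

    def validate(self):
        p = np.asarray(self.response_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
            raise ValueError(f"{self.name}: response probabilities must be a "
                             "3-vector summing to 1")
        if self.cost_6mo_drug < 0 or self.cost_6mo_admin < 0:
            raise ValueError(f"{self.name}: costs must be non-negative")
        for v in self.tot_mean_years.values():
            if v <= 0:
                raise ValueError(f"{self.name}: time-on-treatment means must "
                                 "be positive")


@dataclass
class Strategy:
    """An ordered, non-empty treatment sequence; the last element must be
    terminal (absorbing)."""

    label: str
    treatments: list

    def validate(self):
        if not self.treatments:
            raise ValueError("strategy sequence must be non-empty")
        if not self.treatments[-1].is_terminal:
            raise ValueError("final treatment in a sequence must be terminal")
        for t in self.treatments:
            t.validate()


@dataclass
class EconConfig:
    """Economic model settings (illustrative defaults, UK conventions)."""

    horizon_years: float = 40.0
    discount_rate_costs: float = 0.035
    discount_rate_qalys: float = 0.035
    utility_intercept: float = 0.89
    utility_haq_slope: float = -0.28
    utility_bounds: tuple = (-0.5, 1.0)
    haq_progression_nbt: float = 0.045        # HAQ points per year
    mortality_baseline_hazard: float = 0.02   # annual
    mortality_hr_per_haq: float = 1.33
    baseline_haq_mean: float = 1.9
    baseline_haq_sd: float = 0.5
    n_individuals: int = 2000
    psa_iterations: int = 600
    seed: int = 0
    wtp_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0, 100001, 2500, dtype=float))
    common_random_numbers: bool = True

    def validate(self):
        if self.discount_rate_costs < 0 or self.discount_rate_qalys < 0:
            raise ValueError("discount rates must be non-negative")
        lo, hi = self.utility_bounds
        if not -0.5 <= lo < hi <= 1.0:
            raise ValueError("utility bounds must satisfy -0.5 <= lo < hi <= 1")
        if np.any(np.diff(self.wtp_grid) <= 0):
            raise ValueError("willingness-to-pay grid must be increasing")
        if self.horizon_years <= 0 or self.n_individuals <= 0:
            raise ValueError("horizon and cohort size must be positive")


def default_nbt_params() -> TreatmentParams:
    return TreatmentParams("NBT", response_probs=(0.6, 0.3, 0.1),
                           cost_6mo_drug=150.0, cost_6mo_admin=100.0,
                           is_terminal=True)


def default_biologic_strategy(rtx_response=(0.35, 0.50, 0.15),
                              first_line_response=(0.32, 0.48, 0.20)) -> Strategy:
    """First-line biologic, second-line rituximab, then nonbiologic
    therapy.  ``rtx_response`` is the (none, moderate, good) probability
    vector for rituximab, typically supplied from an evidence source."""
    first = TreatmentParams("biologic", tuple(first_line_response),
                            cost_6mo_drug=4600.0, cost_6mo_admin=300.0)
    rtx = TreatmentParams("RTX", tuple(rtx_response),
                          cost_6mo_drug=3500.0, cost_6mo_admin=450.0)
    return Strategy("biologic", [first, rtx, default_nbt_params()])


def default_nbt_strategy() -> Strategy:
    return Strategy("NBT", [default_nbt_params()])


# ---------------------------------------------------------------------------
# numerical pieces
# ---------------------------------------------------------------------------

def _disc_integral(u0: float, slope: float, t0: float, t1: float,
                   delta: float) -> float:
    """integral of (u0 + slope*(t-t0)) * exp(-delta*t) dt over [t0, t1]."""
    if t1 <= t0:
        return 0.0
    if delta == 0.0:
        dt = t1 - t0
        return u0 * dt + 0.5 * slope * dt * dt
    e0, e1 = math.exp(-delta * t0), math.exp(-delta * t1)
    base = u0 * (e0 - e1) / delta
    dt = t1 - t0
    ramp = slope * ((e0 - e1) / delta ** 2 - dt * e1 / delta)
    return base + ramp


def _utility(haq: float, config: EconConfig) -> float:
    u = config.utility_intercept + config.utility_haq_slope * haq
    return float(np.clip(u, *config.utility_bounds))


class _DeathClock:
    """Cumulative-hazard death sampler: death occurs when the integrated
    hazard reaches a pre-drawn exponential threshold, so a uniformly
    lower hazard path always postpones death."""

    def __init__(self, u_death: float):
        self.remaining = -math.log(max(u_death, 1e-300))

    def advance(self, hazard: float, duration: float):
        """Returns time lived within this constant-hazard segment, and
        whether the individual died in it."""
        if duration <= 0:
            return 0.0, False
        burden = hazard * duration
        if self.remaining <= burden:
            lived = self.remaining / hazard if hazard > 0 else duration
            self.remaining = 0.0
            return lived, True
        self.remaining -= burden
        return duration, False


# ---------------------------------------------------------------------------
# individual simulation
# ---------------------------------------------------------------------------

@dataclass
class _Uniforms:
    """Fixed per-individual pool of decision uniforms (common random
    numbers across strategies)."""

    haq0: float
    u_death: float
    u_category: np.ndarray   # one per treatment slot
    u_duration: np.ndarray   # one per treatment slot

    @classmethod
    def draw(cls, rng: np.random.Generator, config: EconConfig,
             max_slots: int = 8) -> "_Uniforms":
        haq0 = float(np.clip(rng.normal(config.baseline_haq_mean,
                                        config.baseline_haq_sd), 0.0, 3.0))
        return cls(haq0, float(rng.random()), rng.random(max_slots),
                   rng.random(max_slots))


def _draw_category(u: float, probs) -> str:
    """Cumulative-from-the-top inversion: improving the response
    distribution maps the same uniform to the same or a better category."""
    p_none, p_mod, p_good = probs
    if u < p_good:
        return "good"
    if u < p_good + p_mod:
        return "moderate"
    return "none"


def simulate_individual(uniforms: _Uniforms, strategy: Strategy,
                        config: EconConfig, record_trace: bool = False):
    """Simulate one lifetime under a strategy.

    Returns ``(cost, qaly, trace)``: discounted lifetime cost and QALY
    and, when requested, the full event trace (each entry carries the
    event time, a label, the undiscounted cost charged and the
    discounted cost/QALY increments, so totals can be audited).
    """
    d_c = math.log1p(config.discount_rate_costs)
    d_q = math.log1p(config.discount_rate_qalys)
    horizon = config.horizon_years

    t = 0.0
    haq = uniforms.haq0
    clock = _DeathClock(uniforms.u_death)
    cost = 0.0
    qaly = 0.0
    trace = [] if record_trace else None
    alive = True

    def log(time, event, charge=0.0, dcost=0.0, dqaly=0.0, **kv):
        if trace is not None:
            trace.append({"time": time, "event": event, "charge": charge,
                          "disc_cost": dcost, "disc_qaly": dqaly, **kv})

    def hazard(h):
        return config.mortality_baseline_hazard * config.mortality_hr_per_haq ** h

    def charge_periods(tp: TreatmentParams, start: float, stop: float):
        """Charge drug+administration cost at the start of each 6-month
        period begun within [start, stop)."""
        nonlocal cost
        per = tp.cost_6mo_drug + tp.cost_6mo_admin
        k = 0
        while start + k * PERIOD_YEARS < stop - 1e-12 or k == 0:
            when = start + k * PERIOD_YEARS
            if when >= stop and k > 0:
                break
            dc = per * math.exp(-d_c * when)
            cost += dc
            log(when, f"cost:{tp.name}", charge=per, dcost=dc)
            k += 1

    def live_constant(h_now: float, u_now: float, start: float, stop: float):
        """Live through a constant-HAQ segment; returns the actual end
        time and aliveness."""
        nonlocal qaly, alive
        stop = min(stop, horizon)
        lived, died = clock.advance(hazard(h_now), stop - start)
        end = start + lived
        dq = _disc_integral(u_now, 0.0, start, end, d_q)
        qaly += dq
        log(end, "segment", dqaly=dq, haq=h_now)
        if died:
            alive = False
            log(end, "death")
        return end

    for slot, tp in enumerate(strategy.treatments):
        if not alive or t >= horizon:
            break
        if tp.is_terminal:
            # absorbing line: HAQ progresses linearly, bounded at 3;
            # advance in 6-month steps with piecewise-constant hazard
            charge_start = t
            seg_start = t
            while alive and t < horizon:
                step_end = min(t + PERIOD_YEARS, horizon)
                u_now = _utility(haq, config)
                rate = config.haq_progression_nbt if haq < 3.0 else 0.0
                # utility within the step uses the segment-average HAQ
                haq_end = min(3.0, haq + rate * (step_end - t))
                u_end = _utility(haq_end, config)
                slope = ((u_end - u_now) / (step_end - t)) if step_end > t else 0.0
                lived, died = clock.advance(hazard(haq), step_end - t)
                end = t + lived
                dq = _disc_integral(u_now, slope, t, end, d_q)
                qaly += dq
                log(end, "segment", dqaly=dq, haq=haq)
                haq = min(3.0, haq + rate * lived)
                t = end
                if died:
                    alive = False
                    log(end, "death")
                if end >= step_end - 1e-12 and alive:
                    continue
                break
            charge_periods(tp, charge_start, t)
            break

        # active line: assessment after six months on treatment
        start_line = t
        haq_enter = haq
        assess_end = min(t + ASSESSMENT_YEARS, horizon)
        t = live_constant(haq, _utility(haq, config), t, assess_end)
        if not alive or t >= horizon:
            charge_periods(tp, start_line, t)
            break
        category = _draw_category(uniforms.u_category[slot], tp.response_probs)
        log(t, f"assessment:{tp.name}", category=category)
        if category == "none":
            charge_periods(tp, start_line, t)
            continue  # immediate switch to the next line
        haq = float(np.clip(haq_enter + tp.haq_change[category], 0.0, 3.0))
        mean_tot = tp.tot_mean_years[category]
        u = max(uniforms.u_duration[slot], 1e-300)
        duration = -mean_tot * math.log(u)
        stop_line = min(t + duration, horizon)
        t = live_constant(haq, _utility(haq, config), t, stop_line)
        charge_periods(tp, start_line, t)
        haq = haq_enter  # rebound of the on-treatment gain at discontinuation
        if not alive:
            break

    return cost, qaly, trace


def audit_trace(trace) -> dict:
    """Re-sum a trace's discounted increments (conservation check)."""
    return {"cost": sum(e["disc_cost"] for e in trace),
            "qaly": sum(e["disc_qaly"] for e in trace)}


# ---------------------------------------------------------------------------
# cohorts and PSA
# ---------------------------------------------------------------------------

def _individual_uniforms(seed: int, i: int, config: EconConfig) -> _Uniforms:
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, i]))
    return _Uniforms.draw(rng, config)


def run_cohort(strategy: Strategy, config: EconConfig, seed: int | None = None,
               n_individuals: int | None = None) -> dict:
    """Mean discounted lifetime cost and QALY over a simulated cohort,
    with Monte-Carlo standard errors.  Cohorts run with the same seed
    share every random draw (common random numbers)."""
    strategy.validate()
    config.validate()
    seed = config.seed if seed is None else seed
    n = n_individuals or config.n_individuals
    costs = np.empty(n)
    qalys = np.empty(n)
    for i in range(n):
        u = _individual_uniforms(seed, i, config)
        costs[i], qalys[i], _ = simulate_individual(u, strategy, config)
    return {"strategy": strategy.label,
            "mean_cost": float(costs.mean()), "mean_qaly": float(qalys.mean()),
            "se_cost": float(costs.std(ddof=1) / np.sqrt(n)),
            "se_qaly": float(qalys.std(ddof=1) / np.sqrt(n)),
            "n_individuals": n}


def average_biologic(results) -> dict:
    """Unweighted mean of cost and QALY across biologic strategies."""
    results = list(results)
    if not results:
        raise ValueError("need at least one biologic strategy result")
    return {"strategy": "biologic-average",
            "mean_cost": float(np.mean([r["mean_cost"] for r in results])),
            "mean_qaly": float(np.mean([r["mean_qaly"] for r in results])),
            "n_strategies": len(results)}


def compute_icer(delta_cost: float, delta_qaly: float) -> dict:
    """Incremental cost-effectiveness ratio with its CE-plane quadrant."""
    if delta_qaly == 0:
        raise ValueError("ICER undefined: incremental QALYs are zero")
    quadrant = {(True, True): "NE", (True, False): "NW",
                (False, True): "SE", (False, False): "SW"}[
        (delta_cost > 0, delta_qaly > 0)]
    return {"icer": delta_cost / delta_qaly, "quadrant": quadrant}


@dataclass
class PSAResult:
    """Per-iteration PSA output for a two-strategy comparison."""

    iterations: pd.DataFrame     # cost/qaly per strategy, delta_*, icer
    labels: tuple                # (comparator, reference) e.g. (biologic, NBT)
    n_individuals: int
    seed: int
    n_undefined_icer: int = 0

    def summary(self) -> dict:
        it = self.iterations
        out = {}
        for col in ("cost_0", "qaly_0", "cost_1", "qaly_1",
                    "delta_cost", "delta_qaly"):
            out[col] = {"mean": float(it[col].mean()),
                        "ci": [float(q) for q in it[col].quantile([0.025, 0.975])]}
        defined = it["icer"].dropna()
        out["icer"] = {"mean": float(defined.mean()) if len(defined) else np.nan,
                       "ci": [float(q) for q in defined.quantile([0.025, 0.975])]
                       if len(defined) else [np.nan, np.nan],
                       "n_undefined": self.n_undefined_icer}
        # ratio-of-means alternative, reported alongside the mean of ratios
        out["icer_of_means"] = (float(it["delta_cost"].mean()
                                      / it["delta_qaly"].mean())
                                if it["delta_qaly"].mean() != 0 else np.nan)
        return out


def run_psa(rtx_inputs, config: EconConfig, n_iterations: int | None = None,
            n_individuals: int | None = None, seed: int | None = None,
            first_line_response=(0.32, 0.48, 0.20),
            sample_structural: bool = True) -> PSAResult:
    """Probabilistic sensitivity analysis comparing the biologic strategy
    (first-line biologic, rituximab, nonbiologic) with the nonbiologic
    strategy.

    Per iteration one parameter set is drawn — rituximab response
    probabilities from ``rtx_inputs`` (posterior draws or a point mass),
    first-line response from a Dirichlet, costs from Gammas, HAQ
    improvements from truncated normals — and both strategies are run on
    the same individuals with common random numbers.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    n_iter = n_iterations or config.psa_iterations
    n_ind = n_individuals or config.n_individuals

    rows = []
    n_undef = 0
    for j in range(n_iter):
        prng = np.random.default_rng(np.random.SeedSequence(
            [seed & 0x7FFFFFFF, 100000 + j]))
        rtx_probs = rtx_inputs.sample(prng, 1)[0]
        if sample_structural:
            fl_probs = prng.dirichlet(np.asarray(first_line_response) * 120)
        else:
            fl_probs = np.asarray(first_line_response, dtype=float)
        bio = default_biologic_strategy(tuple(rtx_probs), tuple(fl_probs))
        if sample_structural:
            for tp in bio.treatments:
                if not tp.is_terminal:
                    tp.cost_6mo_drug = float(prng.gamma(
                        (1 / 0.15) ** 2, tp.cost_6mo_drug * 0.15 ** 2))
                    dm = tp.haq_change["moderate"]
                    dg = tp.haq_change["good"]
                    tp.haq_change["moderate"] = float(min(prng.normal(dm, 0.05), 0.0))
                    tp.haq_change["good"] = float(min(prng.normal(dg, 0.05), 0.0))
        nbt = default_nbt_strategy()

        # with common random numbers the same individuals are reused in
        # every iteration and by both strategies, so iteration-level
        # spread reflects parameter (second-order) uncertainty only
        if config.common_random_numbers:
            seed_b = seed_n = seed & 0x7FFFFFFF
        else:
            seed_b = (seed + j * 131071) & 0x7FFFFFFF
            seed_n = (seed_b + 7919) & 0x7FFFFFFF
        res_b = run_cohort(bio, config, seed=seed_b, n_individuals=n_ind)
        res_n = run_cohort(nbt, config, seed=seed_n, n_individuals=n_ind)
        dc = res_b["mean_cost"] - res_n["mean_cost"]
        dq = res_b["mean_qaly"] - res_n["mean_qaly"]
        icer = dc / dq if dq != 0 else np.nan
        if dq == 0:
            n_undef += 1
        rows.append({"iteration": j,
                     "cost_0": res_b["mean_cost"], "qaly_0": res_b["mean_qaly"],
                     "cost_1": res_n["mean_cost"], "qaly_1": res_n["mean_qaly"],
                     "delta_cost": dc, "delta_qaly": dq, "icer": icer})
    return PSAResult(pd.DataFrame(rows), ("biologic", "NBT"), n_ind, seed,
                     n_undef)


def ceac(psa: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: per willingness-to-pay
    threshold, the fraction of PSA iterations with positive incremental
    net benefit (lambda * dQ - dC > 0)."""
    grid = np.asarray(wtp_grid if wtp_grid is not None
                      else np.arange(0, 100001, 2500), dtype=float)
    dq = psa.iterations["delta_qaly"].to_numpy()
    dc = psa.iterations["delta_cost"].to_numpy()
    prob = [(lam * dq - dc > 0).mean() for lam in grid]
    return pd.DataFrame({"wtp": grid, "probability_cost_effective": prob})


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def ce_plane_plot(psas: dict, path) -> None:
    """Scatter of (incremental QALYs, incremental costs), one point per
    PSA iteration, one colour per labelled analysis."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 5))
    for label, psa in psas.items():
        ax.scatter(psa.iterations["delta_qaly"], psa.iterations["delta_cost"],
                   s=8, alpha=0.6, label=label)
    ax.axhline(0, color="0.6", lw=0.8)
    ax.axvline(0, color="0.6", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental costs (£)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def ceac_plot(curves: dict, path) -> None:
    """Acceptability curves (probability cost-effective vs threshold)."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve["wtp"], curve["probability_cost_effective"], label=label)
    ax.set_xlabel("Willingness-to-pay threshold (£ per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
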