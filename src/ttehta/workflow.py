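"""End-to-end orchestration of the three analysis scenarios.

A scenario names the evidence source feeding the economic model's
rituximab response probabilities:

* ``rct``    — the trial arm alone (printed arm-level inputs);
* ``rwd``    — the target-trial emulation of the synthetic registry alone;
* ``pooled`` — the Bayesian meta-analysis of both.

``run_pipeline`` executes the stages a scenario requires (registry
simulation -> emulation -> causal estimation -> evidence synthesis ->
economic PSA), writes every stage's artifacts under the scenario's
output directory and ties them together in a hashed manifest, so that
re-running with the same configuration and seed yields an identical
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causal_estimation as ce
from . import economic_model as em
from . import evidence_synthesis as es
from .response_criteria import tabulate_responses
from .synthetic_registry import SyntheticConfig, generate_cohort, inject_missingness, write_registry
from .trial_emulation import ProtocolConfig, emulate

__all__ = ["ScenarioConfig", "run_pipeline", "compare_scenarios",
           "round_to_nearest"]

log = logging.getLogger("ttehta")

SCENARIOS = ("rct", "rwd", "pooled")

#: printed arm-level inputs for the rituximab trial arm
REFLEX_RTX = {"n": 298, "p_modplus": 0.650, "p_good": 0.150}


@dataclass
class ScenarioConfig:
    """One analysis scenario: evidence source, sub-configurations, seed."""

    scenario: str = "pooled"
    seed: int = 0
    output_dir: str = "scenario-output"
    n_patients: int = 4000
    m_imputations: int = 5
    psa_iterations: int = 60
    n_individuals: int = 500
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    econ: em.EconConfig = field(default_factory=em.EconConfig)
    mcmc_draws: int = 2000

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        protocol = ProtocolConfig(**raw.pop("protocol", {}))
        econ = em.EconConfig(**raw.pop("econ", {}))
        return cls(protocol=protocol, econ=econ, **raw)


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: ScenarioConfig) -> dict:
    """Run one scenario end to end; returns the artifact bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    bundle = {"scenario": config.scenario, "seed": config.seed,
              "outputs": {}}
    stage = "setup"
    try:
        arms = []
        if config.scenario in ("rwd", "pooled"):
            stage = "simulate-registry"
            log.info("stage %s", stage)
            syn = SyntheticConfig(n_patients=config.n_patients, seed=config.seed)
            cohort = inject_missingness(generate_cohort(syn), syn)
            write_registry(cohort, outdir / "registry")

            stage = "emulate"
            log.info("stage %s", stage)
            dataset, exclusions = emulate(cohort, config.protocol)
            dataset.to_csv(outdir / "emulated_trial.csv", index=False)
            exclusions.to_csv(outdir / "exclusions.csv", index=False)
            counts = tabulate_responses(dataset)
            counts.to_csv(outdir / "arm_counts.csv", index=False)

            stage = "estimate"
            log.info("stage %s", stage)
            estimate = ce.estimate_effect(dataset, adjusted=True,
                                          m=config.m_imputations,
                                          seed=config.seed)
            crude = ce.estimate_effect(dataset, adjusted=False)
            (outdir / "effect_estimate.json").write_text(json.dumps(
                {"adjusted": estimate.to_dict(), "unadjusted": crude.to_dict()},
                indent=2, sort_keys=True))
            bundle["effect_estimate"] = estimate.to_dict()

            probs = estimate.response_probabilities()
            n_rtx = int((dataset["strategy"] == "RTX").sum())
            n_nbt = int((dataset["strategy"] == "NBT").sum())
            r_rtx = ce.reconstruct_counts(n_rtx, probs.loc["RTX", "p_modplus"],
                                          probs.loc["RTX", "p_good"])
            r_nbt = ce.reconstruct_counts(n_nbt, probs.loc["NBT", "p_modplus"],
                                          probs.loc["NBT", "p_good"])
            arms.append(es.ArmCounts("TTE-registry", "RTX", n_rtx,
                                     int(r_rtx[1] + r_rtx[2]), int(r_rtx[2])))
            arms.append(es.ArmCounts("TTE-registry", "NBT", n_nbt,
                                     int(r_nbt[1] + r_nbt[2]), int(r_nbt[2])))

        if config.scenario in ("rct", "pooled"):
            r = ce.reconstruct_counts(REFLEX_RTX["n"], REFLEX_RTX["p_modplus"],
                                      REFLEX_RTX["p_good"])
            arms.append(es.ArmCounts("REFLEX", "RTX", REFLEX_RTX["n"],
                                     int(r[1] + r[2]), int(r[2])))

        stage = "synthesize"
        log.info("stage %s", stage)
        es.write_evidence_table(arms, outdir / "evidence_table.csv")
        posterior = es.fit_conditional_binomial(
            arms, n_draws=config.mcmc_draws, seed=config.seed)
        summary = {t: {c: es.summarize_posterior(posterior, t, c)
                       for c in ("p_modplus", "p_good")}
                   for t in posterior.treatments}
        (outdir / "posterior_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        bundle["posterior"] = summary
        rtx_inputs = es.posterior_to_econ_inputs(
            posterior, "RTX",
            {"rct": "rct-only", "rwd": "rwd-only", "pooled": "pooled"}[config.scenario])

        stage = "psa"
        log.info("stage %s", stage)
        psa = em.run_psa(rtx_inputs, config.econ,
                         n_iterations=config.psa_iterations,
                         n_individuals=config.n_individuals,
                         seed=config.seed)
        psa.iterations.to_csv(outdir / "psa_iterations.csv", index=False)
        psa_summary = psa.summary()
        (outdir / "psa_summary.json").write_text(
            json.dumps(psa_summary, indent=2, sort_keys=True, default=float))
        curve = em.ceac(psa, config.econ.wtp_grid)
        curve.to_csv(outdir / "ceac.csv", index=False)
        em.ce_plane_plot({config.scenario: psa}, outdir / "ce_plane.svg")
        em.ceac_plot({config.scenario: curve}, outdir / "ceac.svg")
        bundle["psa"] = psa_summary
        bundle["ceac"] = curve
        bundle["wtp_grid"] = np.asarray(config.econ.wtp_grid, dtype=float)

        stage = "manifest"
        outputs = sorted(p for p in outdir.rglob("*")
                         if p.is_file() and p.suffix in
                         (".csv", ".json") and p.name != "manifest.json")
        manifest = {
            "scenario": config.scenario,
            "seed": config.seed,
            "config": json.loads(json.dumps(dataclasses.asdict(config),
                                            default=str)),
            "files": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        bundle["manifest"] = manifest
        bundle["output_dir"] = str(outdir)
        log.info("scenario %s complete", config.scenario)
        return bundle
    except Exception:
        log.exception("stage %r failed", stage)
        partial = sorted(str(p.relative_to(outdir))
                         for p in outdir.rglob("*") if p.is_file())
        (outdir / "manifest.partial.json").write_text(json.dumps(
            {"failed_stage": stage, "partial_outputs": partial}, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed "
                           f"(partial manifest written)") from None
    finally:
        log.removeHandler(handler)
        handler.close()


def round_to_nearest(x: float, unit: int = 100) -> float:
    """Round to the nearest multiple of ``unit`` (half away from zero),
    the convention used for reported costs and ICERs."""
    return float(np.floor(abs(x) / unit + 0.5) * unit * np.sign(x))


def compare_scenarios(bundles, round_costs_to: int | None = 100):
    """Cross-scenario comparison table of QALYs, costs and ICERs, plus a
    combined acceptability-curve figure when an output directory is
    present in the bundles."""
    bundles = list(bundles)
    if len(bundles) < 2:
        raise ValueError("need at least two scenario bundles to compare")
    grids = [np.asarray(b["wtp_grid"], dtype=float) for b in bundles]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("scenario bundles use mismatched "
                             "willingness-to-pay grids")

    rows = []
    for b in bundles:
        s = b["psa"]
        r = (lambda v: round_to_nearest(v, round_costs_to)) \
            if round_costs_to else (lambda v: v)
        rows.append({
            "scenario": b["scenario"],
            "qaly_biologic": round(s["qaly_0"]["mean"], 2),
            "qaly_nbt": round(s["qaly_1"]["mean"], 2),
            "cost_biologic": r(s["cost_0"]["mean"]),
            "cost_nbt": r(s["cost_1"]["mean"]),
            "icer": r(s["icer"]["mean"]),
        })
    return pd.DataFrame(rows)
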