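"""Target-trial protocol applied to a registry cohort.

The protocol of the hypothetical trial being emulated: adults with
rheumatoid arthritis who stopped one allowed first-line biologic, have
active disease (DAS28 > 3.2) and remain on methotrexate are assigned to
either starting a second-line rituximab course or continuing nonbiologic
therapy for at least 20 weeks.  The participant's baseline is the date
the assigned strategy started (rituximab initiation, or the first-line
stop date for the nonbiologic arm); follow-up is a fixed number of weeks
later; DAS28 measurements are taken from the registry visits closest to
the protocol dates.

Eligibility predicates are evaluated in a fixed, documented order so
that each excluded candidate carries exactly one primary reason code:

1. ``prior_biologic_not_allowed`` — never stopped an allowed first-line
   biologic (covers a rituximab-only biologic history);
2. ``no_qualifying_strategy`` — started a non-rituximab biologic before
   the nonbiologic persistence window elapsed;
3. ``no_baseline_visit`` — no registry visit within the visit-gap
   tolerance of the baseline date (covers patients without visits);
4. ``low_disease_activity`` — baseline DAS28 not greater than the
   threshold (strict inequality);
5. ``no_mtx_at_baseline`` — no methotrexate episode spanning baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response_criteria import classify_eular
from .synthetic_registry import COVARIATE_COLUMNS, RegistryCohort

__all__ = [
    "ProtocolConfig",
    "apply_eligibility",
    "assign_strategy",
    "map_visits",
    "restrict_to_adherent",
    "emulate",
]

DEFAULT_ALLOWED_BIOLOGICS = ("ABT", "ADA", "CTZ", "ETN", "GOL", "IFX", "TCZ")

REASON_ORDER = [
    "prior_biologic_not_allowed",
    "no_qualifying_strategy",
    "no_baseline_visit",
    "low_disease_activity",
    "no_mtx_at_baseline",
]


@dataclass
class ProtocolConfig:
    """Target-trial protocol settings."""

    das28_eligibility_threshold: float = 3.2
    allowed_prior_biologics: tuple = DEFAULT_ALLOWED_BIOLOGICS
    require_mtx_at_baseline: bool = True
    nbt_min_persistence_weeks: int = 20
    followup_weeks: int = 24
    max_visit_gap_days: int = 90
    #: "first" enrols a dual-qualifying patient in the strategy they
    #: qualified for first (the nonbiologic arm); "rtx" prefers rituximab
    dual_enrollment_preference: str = "first"

    def __post_init__(self):
        if self.das28_eligibility_threshold <= 0:
            raise ValueError("das28_eligibility_threshold must be positive")
        if self.followup_weeks <= 0:
            raise ValueError("followup_weeks must be positive")
        if self.dual_enrollment_preference not in ("first", "rtx"):
            raise ValueError("dual_enrollment_preference must be 'first' or 'rtx'")

    @property
    def followup_days(self) -> int:
        return 7 * self.followup_weeks

    @property
    def persistence_days(self) -> int:
        return 7 * self.nbt_min_persistence_weeks


def _candidate_strategies(cohort: RegistryCohort,
                          protocol: ProtocolConfig) -> pd.DataFrame:
    """Per patient: the stopped first-line biologic, the candidate
    strategy and its baseline date (NaT when no strategy qualifies)."""
    eps = cohort.episodes
    allowed = set(protocol.allowed_prior_biologics)
    biologic_labels = allowed | {"RTX"}

    first_line = (eps[eps["drug_label"].isin(allowed) & eps["stop_date"].notna()]
                  .sort_values(["patient_id", "start_date"], kind="stable")
                  .groupby("patient_id", as_index=False).first()
                  .rename(columns={"stop_date": "first_line_stop",
                                   "drug_label": "first_line_drug"})
                  [["patient_id", "first_line_drug", "first_line_stop"]])

    out = cohort.patients[["patient_id"]].merge(first_line, on="patient_id",
                                                how="left")

    bio = eps[eps["drug_label"].isin(biologic_labels)].merge(
        first_line, on="patient_id", how="inner")
    bio = bio[bio["start_date"] >= bio["first_line_stop"]]
    # first subsequent biologic of any kind, and first subsequent rituximab
    nxt = (bio.sort_values(["patient_id", "start_date"], kind="stable")
           .groupby("patient_id", as_index=False).first()
           [["patient_id", "drug_label", "start_date"]]
           .rename(columns={"drug_label": "next_drug", "start_date": "next_start"}))
    rtx = (bio[bio["drug_label"] == "RTX"]
           .sort_values(["patient_id", "start_date"], kind="stable")
           .groupby("patient_id", as_index=False).first()
           [["patient_id", "start_date"]].rename(columns={"start_date": "rtx_start"}))
    out = out.merge(nxt, on="patient_id", how="left").merge(rtx, on="patient_id",
                                                            how="left")

    gap = (out["next_start"] - out["first_line_stop"]).dt.days
    within = out["next_start"].notna() & (gap < protocol.persistence_days)
    out["strategy"] = None
    out["baseline_date"] = pd.NaT

    # a biologic started before the persistence window elapsed
    rtx_quick = within & (out["next_drug"] == "RTX")
    out.loc[rtx_quick, "strategy"] = "RTX"
    out.loc[rtx_quick, "baseline_date"] = out.loc[rtx_quick, "rtx_start"]

    # persisted on nonbiologic therapy for the full window
    nbt_ok = out["first_line_stop"].notna() & ~within
    if protocol.dual_enrollment_preference == "rtx":
        switch = nbt_ok & out["rtx_start"].notna()
        out.loc[switch, "strategy"] = "RTX"
        out.loc[switch, "baseline_date"] = out.loc[switch, "rtx_start"]
        nbt_ok = nbt_ok & ~switch
    out.loc[nbt_ok, "strategy"] = "NBT"
    out.loc[nbt_ok, "baseline_date"] = out.loc[nbt_ok, "first_line_stop"]
    return out


def _nearest_visit(cohort: RegistryCohort, targets: pd.DataFrame,
                   date_col: str) -> pd.DataFrame:
    """Attach the visit nearest to ``targets[date_col]`` per patient,
    breaking distance ties toward the earlier visit.  Adds columns
    ``visit_date``, ``das28`` and ``gap_days``."""
    visits = cohort.visits[["patient_id", "date", "das28"]].sort_values(
        ["date", "patient_id"], kind="stable")
    left = targets[["patient_id", date_col]].reset_index()
    left = left[left[date_col].notna()].sort_values(
        [date_col, "patient_id"], kind="stable")
    back = pd.merge_asof(left, visits, left_on=date_col, right_on="date",
                         by="patient_id", direction="backward")
    fwd = pd.merge_asof(left, visits, left_on=date_col, right_on="date",
                        by="patient_id", direction="forward")
    d_back = (back[date_col] - back["date"]).dt.days.astype("float")
    d_fwd = (fwd["date"] - fwd[date_col]).dt.days.astype("float")
    use_fwd = (d_fwd < d_back.fillna(np.inf)) | d_back.isna()
    chosen_date = back["date"].where(~use_fwd, fwd["date"])
    chosen_das = back["das28"].where(~use_fwd, fwd["das28"])
    gap = d_back.where(~use_fwd, d_fwd)
    res = pd.DataFrame({"index": back["index"], "visit_date": chosen_date,
                        "das28": chosen_das, "gap_days": gap})
    return res.set_index("index").reindex(targets.index)


def apply_eligibility(cohort: RegistryCohort,
                      protocol: ProtocolConfig) -> pd.DataFrame:
    """Evaluate eligibility per patient.

    Returns one row per registry patient with the candidate strategy and
    baseline date, each predicate's verdict, the overall ``eligible``
    flag and the primary ``reason`` code (first failed predicate in the
    documented order; empty for eligible patients).
    """
    cand = _candidate_strategies(cohort, protocol)
    cand["has_first_line_stop"] = cand["first_line_stop"].notna()
    cand["has_strategy"] = cand["strategy"].notna()

    near = _nearest_visit(cohort, cand, "baseline_date")
    cand["baseline_visit_date"] = near["visit_date"]
    cand["das28_baseline"] = near["das28"]
    cand["baseline_gap_days"] = near["gap_days"]
    cand["has_baseline_visit"] = (near["gap_days"].notna()
                                  & (near["gap_days"] <= protocol.max_visit_gap_days))
    cand["active_disease"] = (cand["das28_baseline"]
                              > protocol.das28_eligibility_threshold).fillna(False)

    mtx = cohort.episodes[cohort.episodes["drug_label"] == "MTX"].merge(
        cand[["patient_id", "baseline_date"]], on="patient_id")
    spans = (mtx["start_date"] <= mtx["baseline_date"]) & (
        mtx["stop_date"].isna() | (mtx["stop_date"] >= mtx["baseline_date"]))
    on_mtx = set(mtx.loc[spans, "patient_id"])
    cand["on_mtx"] = cand["patient_id"].isin(on_mtx)
    if not protocol.require_mtx_at_baseline:
        cand["on_mtx"] = True

    checks = [
        ("prior_biologic_not_allowed", cand["has_first_line_stop"]),
        ("no_qualifying_strategy", cand["has_strategy"]),
        ("no_baseline_visit", cand["has_baseline_visit"]),
        ("low_disease_activity", cand["active_disease"]),
        ("no_mtx_at_baseline", cand["on_mtx"]),
    ]
    reason = np.full(len(cand), "", dtype=object)
    failed = np.zeros(len(cand), dtype=bool)
    for code, ok in checks:
        hit = ~ok.to_numpy(dtype=bool) & ~failed
        reason[hit] = code
        failed |= hit
    cand["eligible"] = ~failed
    cand["reason"] = reason
    return cand


def assign_strategy(cohort: RegistryCohort, protocol: ProtocolConfig,
                    verdicts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the emulated-trial dataset: one row per enrolled participant
    with strategy, protocol dates and baseline covariates."""
    if verdicts is None:
        verdicts = apply_eligibility(cohort, protocol)
    enrolled = verdicts[verdicts["eligible"]].copy()
    dataset = enrolled[["patient_id", "strategy", "baseline_date",
                        "das28_baseline", "baseline_gap_days"]].copy()
    dataset["followup_date"] = (dataset["baseline_date"]
                                + pd.Timedelta(days=protocol.followup_days))
    covs = cohort.patients[["patient_id", "previous_biologic"] + COVARIATE_COLUMNS]
    covs = covs.drop(columns=["das28"])  # protocol baseline DAS28 is visit-attached
    dataset = dataset.merge(covs, on="patient_id", how="left")
    dataset["treated"] = (dataset["strategy"] == "RTX").astype(int)
    return dataset.reset_index(drop=True)


def map_visits(dataset: pd.DataFrame, cohort: RegistryCohort,
               protocol: ProtocolConfig) -> pd.DataFrame:
    """Attach follow-up DAS28 from the visit closest to the follow-up
    date; rows whose closest visit is further than the tolerance are
    flagged ``unmeasurable`` and carry no follow-up value."""
    out = dataset.copy()
    near = _nearest_visit(cohort, out, "followup_date")
    gap_ok = near["gap_days"].notna() & (near["gap_days"] <= protocol.max_visit_gap_days)
    out["das28_followup"] = near["das28"].where(gap_ok)
    out["followup_visit_date"] = near["visit_date"].where(gap_ok)
    out["followup_gap_days"] = near["gap_days"]
    out["unmeasurable"] = ~gap_ok.to_numpy()
    return out


def restrict_to_adherent(dataset: pd.DataFrame, cohort: RegistryCohort,
                         protocol: ProtocolConfig) -> pd.DataFrame:
    """Keep participants who adhered to their assigned strategy through
    follow-up: rituximab not stopped early, and no biologic initiated
    during a nonbiologic participant's follow-up period.  Dropped rows
    are returned too, distinguished by ``adherent_flag``/``drop_reason``."""
    eps = cohort.episodes
    out = dataset.copy()
    out["adherent_flag"] = True
    out["drop_reason"] = ""

    rtx = eps[eps["drug_label"] == "RTX"].merge(
        out[["patient_id", "baseline_date", "followup_date"]], on="patient_id")
    early_stop = (rtx["start_date"] >= rtx["baseline_date"]) & rtx["stop_date"].notna() \
        & (rtx["stop_date"] < rtx["followup_date"])
    stopped = set(rtx.loc[early_stop, "patient_id"])
    hit = (out["strategy"] == "RTX") & out["patient_id"].isin(stopped)
    out.loc[hit, ["adherent_flag", "drop_reason"]] = [False, "rtx_discontinued"]

    biologics = set(DEFAULT_ALLOWED_BIOLOGICS) | {"RTX"}
    bio = eps[eps["drug_label"].isin(biologics)].merge(
        out.loc[out["strategy"] == "NBT",
                ["patient_id", "baseline_date", "followup_date"]], on="patient_id")
    switched = (bio["start_date"] > bio["baseline_date"]) & (
        bio["start_date"] < bio["followup_date"])
    switchers = set(bio.loc[switched, "patient_id"])
    hit = (out["strategy"] == "NBT") & out["patient_id"].isin(switchers)
    out.loc[hit, ["adherent_flag", "drop_reason"]] = [False, "started_biologic_before_followup"]
    return out


def emulate(cohort: RegistryCohort, protocol: ProtocolConfig | None = None,
            adherent_only: bool = True):
    """Run the full emulation pipeline.

    Returns ``(dataset, exclusions)``: the analysis-ready emulated-trial
    dataset (enrolled, measurable, optionally adherence-restricted, with
    the EULAR response classified) and a table of all candidates removed
    at any stage with their reason codes.
    """
    protocol = protocol or ProtocolConfig()
    verdicts = apply_eligibility(cohort, protocol)
    dataset = assign_strategy(cohort, protocol, verdicts)
    dataset = map_visits(dataset, cohort, protocol)
    dataset = restrict_to_adherent(dataset, cohort, protocol)

    exclusions = verdicts.loc[~verdicts["eligible"],
                              ["patient_id", "reason"]].copy()
    drops = []
    if adherent_only:
        drops.append(dataset.loc[~dataset["adherent_flag"],
                                 ["patient_id", "drop_reason"]]
                     .rename(columns={"drop_reason": "reason"}))
        dataset = dataset[dataset["adherent_flag"]].copy()
    unmeasurable = dataset["unmeasurable"]
    drops.append(dataset.loc[unmeasurable, ["patient_id"]]
                 .assign(reason="no_followup_measurement"))
    dataset = dataset[~unmeasurable].copy()
    exclusions = pd.concat([exclusions] + drops, ignore_index=True)

    dataset["eular"] = classify_eular(dataset["das28_baseline"].to_numpy(),
                                      dataset["das28_followup"].to_numpy())
    return dataset.reset_index(drop=True), exclusions
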