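"""Shared fixtures: generated cohorts and a hand-built registry whose
emulation verdicts are known by enumeration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ttehta.synthetic_registry import (COVARIATE_COLUMNS, RegistryCohort,
                                       SyntheticConfig, generate_cohort)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

EPOCH = pd.Timestamp("2001-01-01")


def day(d):
    return EPOCH + pd.Timedelta(days=d)


@pytest.fixture(scope="session")
def cohort_5k():
    """A mid-size complete cohort reused by several test modules."""
    return generate_cohort(SyntheticConfig(n_patients=5000, seed=11,
                                           missingness_rates={}))


@pytest.fixture(scope="session")
def emulated_5k(cohort_5k):
    from ttehta.trial_emulation import ProtocolConfig, emulate
    return emulate(cohort_5k, ProtocolConfig())


def _patient_row(pid, das28=5.5, mtx=10.0, prev="ETN"):
    row = {"patient_id": pid, "registration_date": EPOCH,
           "observation_end_date": day(900), "previous_biologic": prev,
           "female": 1, "age_years": 60.0, "disease_duration_years": 10.0,
           "tjc28": 8.0, "sjc28": 5.0, "esr_mm_hr": 30.0,
           "patient_global_0_100": 60.0, "das28": das28, "haq_0_3": 1.5,
           "rheumatoid_factor_flag": 1, "comorbidity_flag": 0,
           "n_previous_dmards": 3, "n_previous_biologics": 1,
           "stop_reason_inefficacy_flag": 1, "glucocorticoid_flag": 0,
           "mtx_weekly_dose_mg": mtx}
    return row


def _visit(pid, d, das28):
    # components chosen so the composite equals das28 exactly
    return {"patient_id": pid, "date": day(d), "tjc28": 0, "sjc28": 0,
            "esr_mm_hr": float(np.exp(das28 / 0.7)),
            "patient_global_0_100": 0.0, "das28": das28, "haq_0_3": 1.5}


def _episode(pid, drug, start, stop=None, reason=""):
    return {"patient_id": pid, "drug_label": drug, "start_date": day(start),
            "stop_date": day(stop) if stop is not None else pd.NaT,
            "stop_reason": reason}


def build_fixture_cohort():
    """Twelve hand-built trajectories with enumerated emulation verdicts.

    Returns (cohort, expected) where expected maps patient_id to a dict
    with the anticipated fate under the default protocol.
    """
    P, V, E = [], [], []

    def add(pid, visits, episodes, das28=5.5, mtx_stop="open", prev="ETN"):
        P.append(_patient_row(pid, das28=das28, prev=prev))
        V.extend(_visit(pid, d, s) for d, s in visits)
        if mtx_stop == "open":
            E.append(_episode(pid, "MTX", 0))
        elif mtx_stop is not None:
            E.append(_episode(pid, "MTX", 0, mtx_stop))
        E.extend(episodes)

    # 1: clean rituximab participant, good response
    add(1, [(305, 5.5), (478, 3.0)],
        [_episode(1, "ETN", 0, 300, "inefficacy"), _episode(1, "RTX", 310)])
    # 2: clean nonbiologic participant, no response
    add(2, [(300, 5.0), (468, 4.6)], [_episode(2, "ADA", 0, 300, "inefficacy")],
        prev="ADA")
    # 3: DAS28 exactly at the threshold -> excluded (strict inequality)
    add(3, [(310, 3.2)],
        [_episode(3, "ETN", 0, 300, "inefficacy"), _episode(3, "RTX", 310)])
    # 4: prior biologic is rituximab itself -> not an allowed first line
    add(4, [(305, 6.0)],
        [_episode(4, "RTX", 0, 300, "inefficacy"), _episode(4, "RTX", 310)],
        prev="RTX")
    # 5: new non-rituximab biologic after 19 weeks -> neither strategy
    add(5, [(300, 5.8)],
        [_episode(5, "ADA", 0, 300, "inefficacy"), _episode(5, "ETN", 433)],
        prev="ADA")
    # 6: biologic in weeks 20-24 -> enrolled NBT but non-adherent
    add(6, [(295, 5.8), (470, 5.0)],
        [_episode(6, "ADA", 0, 300, "inefficacy"), _episode(6, "ETN", 440)],
        prev="ADA")
    # 7: nonbiologic >= 20 weeks then rituximab after follow-up ->
    #    enrolled in the nonbiologic arm (single-enrollment tie-break)
    add(7, [(300, 5.6), (466, 5.2)],
        [_episode(7, "ADA", 0, 300, "inefficacy"), _episode(7, "RTX", 500)],
        prev="ADA")
    # 8: rituximab stopped at week ~13 of 24 -> non-adherent
    add(8, [(305, 5.5), (478, 3.0)],
        [_episode(8, "ETN", 0, 300, "inefficacy"),
         _episode(8, "RTX", 310, 400, "adverse_event")])
    # 9: methotrexate stopped before baseline -> ineligible
    add(9, [(310, 6.0)],
        [_episode(9, "ETN", 0, 300, "inefficacy"), _episode(9, "RTX", 310)],
        mtx_stop=200)
    # 10: no visit anywhere near baseline
    add(10, [(700, 5.5)],
        [_episode(10, "ETN", 0, 300, "inefficacy"), _episode(10, "RTX", 310)])
    # 11: baseline measured, follow-up visit far outside tolerance
    add(11, [(310, 5.5)],
        [_episode(11, "ETN", 0, 300, "inefficacy"), _episode(11, "RTX", 310)])
    # 12: two visits equidistant from baseline -> earlier one wins
    add(12, [(290, 6.0), (310, 5.0), (470, 4.7)],
        [_episode(12, "ADA", 0, 300, "inefficacy")], prev="ADA")

    cohort = RegistryCohort(pd.DataFrame(P), pd.DataFrame(V).sort_values(
        ["patient_id", "date"]).reset_index(drop=True), pd.DataFrame(E))

    expected = {
        1: {"fate": "analysis", "strategy": "RTX", "baseline_day": 310,
            "das28_baseline": 5.5, "das28_followup": 3.0, "eular": 2},
        2: {"fate": "analysis", "strategy": "NBT", "baseline_day": 300,
            "das28_baseline": 5.0, "das28_followup": 4.6, "eular": 0},
        3: {"fate": "excluded", "reason": "low_disease_activity"},
        4: {"fate": "excluded", "reason": "prior_biologic_not_allowed"},
        5: {"fate": "excluded", "reason": "no_qualifying_strategy"},
        6: {"fate": "excluded", "reason": "started_biologic_before_followup"},
        7: {"fate": "analysis", "strategy": "NBT", "baseline_day": 300,
            "das28_baseline": 5.6, "das28_followup": 5.2, "eular": 0},
        8: {"fate": "excluded", "reason": "rtx_discontinued"},
        9: {"fate": "excluded", "reason": "no_mtx_at_baseline"},
        10: {"fate": "excluded", "reason": "no_baseline_visit"},
        11: {"fate": "excluded", "reason": "no_followup_measurement"},
        12: {"fate": "analysis", "strategy": "NBT", "baseline_day": 300,
             "das28_baseline": 6.0, "das28_followup": 4.7, "eular": 1},
    }
    return cohort, expected


@pytest.fixture()
def fixture_cohort():
    return build_fixture_cohort()
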