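"""EULAR response classification from DAS28 measurements.

The EULAR criteria grade the response to treatment on an ordered scale
(none < moderate < good) from two quantities: the DAS28 reached at the
end of follow-up and the improvement (baseline minus follow-up).  The
grid, with the boundary conventions used throughout this package:

===================  ==============  =====================  ==============
endpoint DAS28        improvement      improvement            improvement
                      > 1.2            (0.6, 1.2]             <= 0.6
===================  ==============  =====================  ==============
<= 3.2                good            moderate               none
(3.2, 5.1]            moderate        moderate               none
> 5.1                 moderate        none                   none
===================  ==============  =====================  ==============

Categories are encoded as integers 0 (none), 1 (moderate), 2 (good) so
that the ordering is the natural integer order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EULAR_NONE",
    "EULAR_MODERATE",
    "EULAR_GOOD",
    "EULAR_LABELS",
    "classify_eular",
    "tabulate_responses",
]

EULAR_NONE = 0
EULAR_MODERATE = 1
EULAR_GOOD = 2
EULAR_LABELS = ("none", "moderate", "good")

#: plausible range of the DAS28 composite
DAS28_RANGE = (0.0, 10.0)

#: endpoint thresholds (low disease activity / high disease activity)
ENDPOINT_LOW, ENDPOINT_HIGH = 3.2, 5.1
#: improvement thresholds
IMPROVEMENT_SMALL, IMPROVEMENT_LARGE = 0.6, 1.2


def classify_eular(das28_baseline, das28_followup):
    """Classify EULAR response from baseline and follow-up DAS28.

    Parameters
    ----------
    das28_baseline, das28_followup : float or array-like
        DAS28 scores; both must lie in ``[0, 10]`` and be non-missing.

    Returns
    -------
    int or ndarray of int
        Category codes: 0 = none, 1 = moderate, 2 = good.

    Raises
    ------
    ValueError
        If any score is missing (NaN) or outside the plausible range.
        Invalid inputs are never silently classified as "none".
    """
    b = np.asarray(das28_baseline, dtype=float)
    f = np.asarray(das28_followup, dtype=float)
    scalar = b.ndim == 0 and f.ndim == 0
    b, f = np.atleast_1d(b), np.atleast_1d(f)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up arrays must have the same shape")

    bad = ~np.isfinite(b) | ~np.isfinite(f)
    lo, hi = DAS28_RANGE
    bad |= (b < lo) | (b > hi) | (f < lo) | (f > hi)
    if bad.any():
        idx = np.flatnonzero(bad)[:5].tolist()
        raise ValueError(
            f"invalid DAS28 input at positions {idx}: scores must be finite "
            f"and within [{lo}, {hi}]"
        )

    improvement = b - f
    cat = np.zeros(b.shape, dtype=np.int64)  # default: none
    # moderate: (improvement > 1.2 and endpoint > 3.2)
    #        or (0.6 < improvement <= 1.2 and endpoint <= 5.1)
    cat[(improvement > IMPROVEMENT_LARGE) & (f > ENDPOINT_LOW)] = EULAR_MODERATE
    cat[
        (improvement > IMPROVEMENT_SMALL)
        & (improvement <= IMPROVEMENT_LARGE)
        & (f <= ENDPOINT_HIGH)
    ] = EULAR_MODERATE
    # good: endpoint <= 3.2 and improvement > 1.2
    cat[(improvement > IMPROVEMENT_LARGE) & (f <= ENDPOINT_LOW)] = EULAR_GOOD
    return int(cat[0]) if scalar else cat


def tabulate_responses(dataset: pd.DataFrame, arm_col: str = "strategy",
                       category_col: str = "eular") -> pd.DataFrame:
    """Tabulate ordered EULAR category counts and proportions per arm.

    Returns one row per arm with columns ``n``, ``n_none``, ``n_moderate``,
    ``n_good``, ``p_modplus`` (proportion with at least a moderate
    response), ``p_good`` and an ``empty`` flag for zero-size arms.
    """
    rows = []
    for arm, grp in dataset.groupby(arm_col, sort=True, observed=False):
        cats = np.asarray(grp[category_col])
        n = len(cats)
        counts = [int(np.sum(cats == k)) for k in (EULAR_NONE, EULAR_MODERATE, EULAR_GOOD)]
        if n and sum(counts) != n:
            raise ValueError(f"arm {arm!r} contains category codes outside 0/1/2")
        rows.append({
            "strategy": arm, "n": n,
            "n_none": counts[0], "n_moderate": counts[1], "n_good": counts[2],
            "p_modplus": (counts[1] + counts[2]) / n if n else np.nan,
            "p_good": counts[2] / n if n else np.nan,
            "empty": n == 0,
        })
    return pd.DataFrame(rows)
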