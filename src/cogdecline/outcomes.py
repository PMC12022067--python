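"""Cognitive-decline labels and longitudinal MoCA trajectory taxonomy.

Cognitive decline is a drop of three or more MoCA points from baseline to
the 2-year and/or 4-year follow-up.  On integer MoCA scores this is identical
to "more than 2 points", the phrasing used by the trajectory taxonomy:

* ``stable`` — no baseline->follow-up drop exceeds 2 points;
* ``early_decline`` — drop > 2 at year 2 with the year-4 deficit still > 2;
* ``late_decline`` — drop > 2 only at year 4;
* ``fluctuation`` — drop > 2 at year 2 with recovery to within 2 points of
  baseline by year 4.

Note that fluctuators *are* decliners under the and/or decline label (their
year-2 drop meets the threshold); only stable subjects are non-decliners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LabelingError

__all__ = [
    "TrajectoryLabel",
    "decline_label",
    "classify_trajectory",
    "zscore_bin",
    "change_category",
    "label_cohort",
    "category_frequencies",
]

DECLINE_POINTS = 3  # "three or more points" == "more than 2 points"

CATEGORIES = ("stable", "early_decline", "late_decline", "fluctuation")
DECLINE_CATEGORIES = ("early_decline", "late_decline", "fluctuation")


@dataclass(frozen=True)
class TrajectoryLabel:
    decline: bool
    category: str
    deltas: tuple  # (year2 - baseline, year4 - baseline), MoCA points


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def decline_label(moca_baseline, moca_y2, moca_y4) -> bool:
    """True iff MoCA dropped >= 3 points at year 2 and/or year 4.

    Evaluated only on present follow-ups; with both follow-ups missing the
    subject cannot be labeled and a :class:`LabelingError` is raised (such
    subjects are excluded upstream).
    """
    if _missing(moca_baseline):
        raise LabelingError("baseline MoCA missing")
    if _missing(moca_y2) and _missing(moca_y4):
        raise LabelingError("both follow-up MoCA values missing")
    for follow_up in (moca_y2, moca_y4):
        if not _missing(follow_up):
            if moca_baseline - follow_up >= DECLINE_POINTS:
                return True
    return False


def classify_trajectory(moca_baseline, moca_y2, moca_y4) -> TrajectoryLabel:
    """Assign one of the four trajectory categories (see module docstring).

    Requires all three scores; the boundary case of a year-4 deficit of
    exactly 2 points after an early drop counts as recovered (fluctuation).
    """
    if any(_missing(x) for x in (moca_baseline, moca_y2, moca_y4)):
        raise LabelingError("trajectory classification requires all three scores")
    drop2 = moca_baseline - moca_y2
    drop4 = moca_baseline - moca_y4
    if drop2 > 2:
        category = "early_decline" if drop4 > 2 else "fluctuation"
    elif drop4 > 2:
        category = "late_decline"
    else:
        category = "stable"
    return TrajectoryLabel(
        decline=category in DECLINE_CATEGORIES,
        category=category,
        deltas=(moca_y2 - moca_baseline, moca_y4 - moca_baseline),
    )


def zscore_bin(z: float) -> str:
    """Normative bin: above 0 -> above_average; (-1, 0] -> below_average;
    -1 and below -> abnormal."""
    if not math.isfinite(z):
        raise LabelingError("z-score must be finite")
    if z > 0:
        return "above_average"
    if z > -1:
        return "below_average"
    return "abnormal"


def change_category(delta: int) -> str:
    """Decline iff the score dropped by more than 2 points, improvement iff
    it rose by more than 2, else stable."""
    if delta < -2:
        return "decline"
    if delta > 2:
        return "improvement"
    return "stable"


def label_cohort(
    df: pd.DataFrame,
    baseline_col: str = "moca",
    y2_col: str = "moca_y2",
    y4_col: str = "moca_y4",
    on_missing: str = "drop",
) -> pd.DataFrame:
    """Add ``decline`` (0/1) and ``trajectory`` columns to a cohort.

    Subjects with both follow-ups missing are dropped (``on_missing='drop'``,
    the count is recorded in ``df.attrs['n_unlabelable']``) or raise
    (``on_missing='raise'``).  ``trajectory`` is NaN unless all three scores
    are present.
    """
    if baseline_col not in df.columns or (
        y2_col not in df.columns and y4_col not in df.columns
    ):
        raise LabelingError("cohort lacks baseline and follow-up MoCA columns")
    base = pd.to_numeric(df[baseline_col], errors="coerce")
    y2 = pd.to_numeric(df.get(y2_col), errors="coerce")
    y4 = pd.to_numeric(df.get(y4_col), errors="coerce")
    unlabelable = base.isna() | (y2.isna() & y4.isna())
    if unlabelable.any() and on_missing == "raise":
        raise LabelingError(
            f"{int(unlabelable.sum())} subject(s) lack baseline or both "
            "follow-up MoCA scores"
        )
    out = df.loc[~unlabelable].copy()
    base, y2, y4 = base[~unlabelable], y2[~unlabelable], y4[~unlabelable]
    decline = ((base - y2) >= DECLINE_POINTS) | ((base - y4) >= DECLINE_POINTS)
    out["decline"] = decline.astype(int)
    complete = base.notna() & y2.notna() & y4.notna()
    drop2, drop4 = base - y2, base - y4
    category = np.select(
        [
            complete & (drop2 > 2) & (drop4 > 2),
            complete & (drop2 > 2) & ~(drop4 > 2),
            complete & ~(drop2 > 2) & (drop4 > 2),
            complete,
        ],
        ["early_decline", "fluctuation", "late_decline", "stable"],
        default=None,
    )
    out["trajectory"] = category
    out.attrs["n_unlabelable"] = int(unlabelable.sum())
    return out


def category_frequencies(labeled: pd.DataFrame) -> dict:
    """Trajectory category counts and shares (pie-chart style summary)."""
    counts = labeled["trajectory"].value_counts(dropna=True)
    total = int(counts.sum())
    return {
        "n": total,
        "counts": {c: int(counts.get(c, 0)) for c in CATEGORIES},
        "percent": {
            c: (100.0 * counts.get(c, 0) / total if total else float("nan"))
            for c in CATEGORIES
        },
    }
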