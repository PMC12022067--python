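"""Per-feature diagnostic statistics and the cutoff search.

A binary feature's value as a predictor is summarized by its positive and
negative likelihood ratios,

    LR+ = sensitivity / (1 - specificity),
    LR- = (1 - sensitivity) / specificity,

estimated from the 2x2 table of feature presence against future cognitive
decline.  A feature qualifies as a *risk* factor when LR+ > 2 with presence
odds > 0.01 (ruling in), as *protective* when LR- < 0.5 with presence odds
< 0.99 (ruling out), as *both* when both hold, and is otherwise rejected.

No zero-cell continuity correction is applied by default: when no
non-decliner carries the symptom, LR+ is infinite, carried through as such
(an optional Haldane-Anscombe correction exists for likelihood work).  No
family-wise error control is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EstimationError
from .features import FeatureDefinition, binarize_cohort

__all__ = [
    "FeatureStats",
    "likelihood_ratios",
    "counts_from_vectors",
    "qualify_feature",
    "fisher_exact",
    "spearman_rho",
    "pearson_r",
    "GroupComparison",
    "group_compare",
    "CutoffSearchResult",
    "optimize_cutoff",
    "feature_table",
]

LR_POS_MIN = 2.0
LR_NEG_MAX = 0.5
ODDS_MIN = 0.01
ODDS_MAX = 0.99


@dataclass(frozen=True)
class FeatureStats:
    """2x2 counts and derived diagnostic statistics for one binary feature.

    ``counts`` rows are feature present/absent, columns decline yes/no:
    ``[[a, b], [c, d]]`` with a = decliners with the feature, b =
    non-decliners with the feature, c, d their feature-negative counterparts.
    """

    counts: tuple
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    presence_proportion: float
    presence_odds: float
    fisher_p: float
    name: str = ""

    @property
    def n(self) -> int:
        return int(sum(sum(row) for row in self.counts))


def _ratio(num: float, den: float) -> float:
    if den == 0.0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def likelihood_ratios(
    counts, name: str = "", haldane: bool = False
) -> FeatureStats:
    """Diagnostic statistics from a 2x2 presence-by-outcome table.

    ``counts`` is ``[[a, b], [c, d]]`` as in :class:`FeatureStats`.  With a
    zero false-positive cell and positive true positives LR+ is infinite (all
    symptom carriers correctly identified); a feature nobody carries has both
    sensitivity and 1-specificity zero and LR+ is NaN.  ``haldane=True`` adds
    0.5 to every cell before computing the LRs (never the proportions).
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise EstimationError("counts must be a nonnegative 2x2 table")
    (a, b), (c, d) = table
    n_decline, n_stable = a + c, b + d
    if n_decline == 0 or n_stable == 0:
        raise EstimationError("an outcome class has zero subjects")
    sens = a / n_decline
    spec = d / n_stable
    if haldane:
        ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        sens_h, spec_h = ah / (ah + ch), dh / (bh + dh)
        lr_pos = _ratio(sens_h, 1.0 - spec_h)
        lr_neg = _ratio(1.0 - sens_h, spec_h)
    else:
        lr_pos = _ratio(sens, 1.0 - spec)
        lr_neg = _ratio(1.0 - sens, spec)
    n = table.sum()
    n_pos = a + b
    return FeatureStats(
        counts=((int(a), int(b)), (int(c), int(d))),
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        presence_proportion=n_pos / n,
        presence_odds=_ratio(n_pos, n - n_pos),
        fisher_p=fisher_exact(table),
        name=name,
    )


def counts_from_vectors(present, decline):
    """2x2 presence-by-outcome counts from aligned boolean vectors."""
    present = np.asarray(present, dtype=bool)
    decline = np.asarray(decline, dtype=bool)
    if present.shape != decline.shape:
        raise EstimationError("presence and outcome vectors differ in length")
    a = int(np.sum(present & decline))
    b = int(np.sum(present & ~decline))
    c = int(np.sum(~present & decline))
    d = int(np.sum(~present & ~decline))
    return ((a, b), (c, d))


def qualify_feature(stats: FeatureStats) -> str:
    """Assign the feature's role from its likelihood ratios and prevalence.

    The 0.01/0.99 prevalence guards act on the presence proportion: a risk
    feature must be carried by more than 1% of subjects, a protective one by
    fewer than 99% (so its absence is informative for somebody).  Reading the
    upper guard as a literal presence-odds bound would disqualify the
    normal-olfaction feature (proportion 0.82, odds 4.47), which the study
    selects as its strongest protective factor, so proportion is the
    operative scale.
    """
    # NaN comparisons are False, so a never-present feature (LR+ = NaN) and
    # an always-present one fall through to "rejected" naturally.
    risk = stats.lr_pos > LR_POS_MIN and stats.presence_proportion > ODDS_MIN
    protective = (
        stats.lr_neg < LR_NEG_MAX and stats.presence_proportion < ODDS_MAX
    )
    if risk and protective:
        return "both"
    if risk:
        return "risk"
    if protective:
        return "protective"
    return "rejected"


def fisher_exact(counts, alternative: str = "two-sided") -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise EstimationError("counts must be a nonnegative 2x2 table")
    return float(sps.fisher_exact(table, alternative=alternative)[1])


def spearman_rho(x, y):
    """Spearman rank correlation (rho, two-sided p)."""
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def pearson_r(x, y):
    """Pearson correlation (r, two-sided p)."""
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class GroupComparison:
    """Normality-gated two-group comparison report."""

    test: str  # "t" or "wilcoxon_rank_sum"
    statistic: float
    p: float
    reason: str
    shapiro_p: tuple | None = None


def group_compare(values, labels, discrete: bool = False) -> GroupComparison:
    """Compare a variable between two outcome groups.

    Shapiro-Wilk gates the choice of test: both groups normal (p > 0.05) ->
    two-sample t test; otherwise the Wilcoxon rank-sum (Mann-Whitney) test.
    Discrete variables are assumed non-normal and skip the gate, as do
    constant or tiny groups (Shapiro undefined).  Missing values are removed
    before comparison.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        raise EstimationError("group comparison requires two nonempty groups")
    g1, g2 = groups
    shapiro_p = None
    if discrete:
        reason = "discrete variable assumed non-normal"
        normal = False
    elif any(len(g) < 3 or np.ptp(g) == 0 for g in (g1, g2)):
        reason = "normality test not applicable (constant or tiny group)"
        normal = False
    else:
        p1 = float(sps.shapiro(g1).pvalue)
        p2 = float(sps.shapiro(g2).pvalue)
        shapiro_p = (p1, p2)
        normal = p1 > 0.05 and p2 > 0.05
        reason = (
            "both groups pass Shapiro-Wilk"
            if normal
            else "Shapiro-Wilk rejects normality"
        )
    if normal:
        res = sps.ttest_ind(g1, g2)
        return GroupComparison("t", float(res.statistic), float(res.pvalue),
                               reason, shapiro_p)
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided")
    return GroupComparison("wilcoxon_rank_sum", float(res.statistic),
                           float(res.pvalue), reason, shapiro_p)


@dataclass
class CutoffSearchResult:
    cutoff: float | None
    lr_pos: float
    rho: float
    accepted: bool
    reason: str
    candidates: pd.DataFrame = field(repr=False, default=None)


def optimize_cutoff(
    values,
    outcomes,
    hypothesis_sign: int,
    min_odds: float = ODDS_MIN,
    consistency_floor: float = 0.7,
    strategy: str = "lr_pos",
) -> CutoffSearchResult:
    """Iterative cutoff search with a hypothesis-consistency guard.

    Every distinct observed value is a candidate cutoff; presence is
    ``value > cutoff`` for a positive hypothesis sign and ``value < cutoff``
    for a negative one.  Among candidates whose presence odds exceed
    ``min_odds`` the cutoff maximizing LR+ is returned (``strategy='lr_pos'``
    is the only shipped strategy; the switch isolates the choice).  To guard
    against overfitting, the Spearman correlation between candidate cutoff
    and induced LR+ must have the hypothesized sign and magnitude at least
    ``consistency_floor``, otherwise the search is rejected.
    """
    if strategy != "lr_pos":
        raise EstimationError(f"unknown cutoff-search strategy {strategy!r}")
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    keep = ~np.isnan(values)
    values, outcomes = values[keep], outcomes[keep]
    grid = np.unique(values)
    if grid.size < 2:
        return CutoffSearchResult(None, float("nan"), float("nan"), False,
                                  "fewer than 2 distinct values")
    rows = []
    for cut in grid:
        present = values > cut if hypothesis_sign > 0 else values < cut
        n_pos = int(present.sum())
        odds = _ratio(n_pos, present.size - n_pos)
        if n_pos == 0:
            continue
        st = likelihood_ratios(counts_from_vectors(present, outcomes))
        rows.append((float(cut), st.lr_pos, odds, odds > min_odds))
    candidates = pd.DataFrame(
        rows, columns=["cutoff", "lr_pos", "odds", "eligible"]
    )
    eligible = candidates[candidates["eligible"]]
    if eligible.empty:
        return CutoffSearchResult(None, float("nan"), float("nan"), False,
                                  "no candidate satisfies the odds bound",
                                  candidates)
    finite = candidates[np.isfinite(candidates["lr_pos"])]
    if len(finite) >= 2 and finite["lr_pos"].nunique() > 1:
        rho, _ = spearman_rho(finite["cutoff"], finite["lr_pos"])
    else:
        rho = float("nan")
    best = eligible.loc[eligible["lr_pos"].idxmax()]
    consistent = (
        np.isfinite(rho)
        and np.sign(rho) == np.sign(hypothesis_sign)
        and abs(rho) >= consistency_floor
    )
    reason = (
        "consistent with hypothesis"
        if consistent
        else "cutoff-LR+ trend inconsistent with hypothesis"
    )
    return CutoffSearchResult(
        float(best["cutoff"]), float(best["lr_pos"]), float(rho)
        if np.isfinite(rho) else float("nan"), bool(consistent), reason,
        candidates,
    )


def feature_table(
    df: pd.DataFrame,
    defs: list[FeatureDefinition],
    label_col: str = "decline",
    haldane: bool = False,
) -> pd.DataFrame:
    """Per-feature summary (LR+, LR-, proportion, Fisher p, role) for a
    labeled cohort — one row per feature definition."""
    presence = binarize_cohort(df, defs)
    decline = df[label_col].astype(bool).to_numpy()
    rows = []
    for d in defs:
        st = likelihood_ratios(
            counts_from_vectors(presence[d.name].to_numpy(), decline),
            name=d.name,
            haldane=haldane,
        )
        rows.append(
            {
                "feature": d.name,
                "description": d.description,
                "lr_pos": round(st.lr_pos, 2),
                "lr_neg": round(st.lr_neg, 2),
                "proportion": round(st.presence_proportion, 2),
                "fisher_p": st.fisher_p,
                "role": qualify_feature(st),
            }
        )
    return pd.DataFrame(rows)
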