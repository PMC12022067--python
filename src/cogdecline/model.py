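"""Likelihood-ratio naive Bayes prognosis with age-bracket priors.

The model starts from a pre-test probability of cognitive decline taken from
the patient's age-of-onset bracket (the decliner proportion within 5-year
intervals, pooled across cohorts for smoother estimates; the whole-dataset
proportion serves as fallback when age is missing), converts it to odds, and
multiplies in one likelihood-ratio factor per qualified feature:

    o = pi / (1 - pi);  o *= LR+ if present (risk), o *= LR- if absent
    (protective);  posterior = o / (1 + o).

A feature whose negative side did not qualify contributes nothing when
absent — which is exactly how the published four-question model behaves,
whose members' LR- all fail the < 0.5 rule, and what neutralizes stroke by
"accounting for it as non-present".  An infinite LR+ on a present feature
forces the posterior to one.

Model reduction uses the likelihood-ratio test statistic (LRTS): the
Bernoulli log-likelihood of the observed outcomes under the model posteriors
is compared with and without each feature; 2 * (LL_full - LL_reduced) is
referred to chi-squared with 1 df, and the least significant feature is
removed per pass until all survivors are significant at alpha.  Redundant
same-hypothesis features (Jaccard index > 0.5) are removed beforehand.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ConfigurationError,
    ContractError,
    EstimationError,
    IndeterminateEvidenceError,
)
from .features import FeatureDefinition, binarize_cohort
from .lrstats import counts_from_vectors, likelihood_ratios, qualify_feature

__all__ = [
    "DEFAULT_BRACKETS",
    "AgeBracketPriors",
    "ModelFeature",
    "PrognosticModel",
    "estimate_priors",
    "posterior_probability",
    "predict_label",
    "model_log_likelihood",
    "lrts_backward_elimination",
    "jaccard_index",
    "redundancy_filter",
    "fit_model",
    "published_model",
    "LRTS_CRITICAL",
]

# Age-of-onset grid: [30,40), then 5-year half-open intervals, ending [75,100).
DEFAULT_BRACKETS = tuple(
    [(30.0, 40.0)]
    + [(float(a), float(a + 5)) for a in range(40, 75, 5)]
    + [(75.0, 100.0)]
)

# 95% quantile of chi-squared with 1 df.
LRTS_CRITICAL = float(sps.chi2.ppf(0.95, df=1))

EPS = 1e-12


@dataclass
class AgeBracketPriors:
    """Pre-test probabilities of decline per age-of-onset bracket.

    ``prior_per_bracket`` entries may be NaN for empty brackets; lookups then
    fall back to ``overall_prior`` (as they do for missing age of onset).
    """

    brackets: list
    n_per_bracket: list
    decliners_per_bracket: list
    overall_n: int
    overall_decliners: int

    def __post_init__(self):
        spans = sorted(tuple(b) for b in self.brackets)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if hi1 > lo2:
                raise ConfigurationError("age brackets overlap")
        for lo, hi in spans:
            if not (lo < hi):
                raise ConfigurationError("age bracket bounds must increase")

    @property
    def prior_per_bracket(self) -> list:
        return [
            (d / n if n else float("nan"))
            for d, n in zip(self.decliners_per_bracket, self.n_per_bracket)
        ]

    @property
    def overall_prior(self) -> float:
        if self.overall_n == 0:
            raise EstimationError("no labeled subjects to estimate a prior")
        return self.overall_decliners / self.overall_n

    def lookup(self, age_of_onset) -> float:
        """Bracket prior for an age of onset; overall prior when the age is
        missing, outside every bracket, or its bracket is empty."""
        if age_of_onset is None or (
            isinstance(age_of_onset, float) and math.isnan(age_of_onset)
        ):
            return self.overall_prior
        for (lo, hi), n, d in zip(
            self.brackets, self.n_per_bracket, self.decliners_per_bracket
        ):
            if lo <= age_of_onset < hi:
                return d / n if n else self.overall_prior
        return self.overall_prior

    def lookup_vector(self, ages: np.ndarray) -> np.ndarray:
        out = np.full(len(ages), self.overall_prior, dtype=float)
        ages = np.asarray(ages, dtype=float)
        for (lo, hi), n, d in zip(
            self.brackets, self.n_per_bracket, self.decliners_per_bracket
        ):
            if n:
                out[(ages >= lo) & (ages < hi)] = d / n
        return out

    def to_dict(self) -> dict:
        return {
            "brackets": [list(b) for b in self.brackets],
            "n_per_bracket": list(self.n_per_bracket),
            "decliners_per_bracket": list(self.decliners_per_bracket),
            "overall_n": self.overall_n,
            "overall_decliners": self.overall_decliners,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "AgeBracketPriors":
        return cls(
            brackets=[tuple(b) for b in raw["brackets"]],
            n_per_bracket=raw["n_per_bracket"],
            decliners_per_bracket=raw["decliners_per_bracket"],
            overall_n=raw["overall_n"],
            overall_decliners=raw["overall_decliners"],
        )


def estimate_priors(
    cohorts,
    brackets=DEFAULT_BRACKETS,
    label_col: str = "decline",
    age_col: str = "age_of_onset",
) -> AgeBracketPriors:
    """Pool one or more labeled cohorts into per-bracket priors.

    Pooling sums decliner and total counts across cohorts per bracket; the
    overall prior pools every labeled subject, including those with a missing
    age of onset (who contribute to no bracket).
    """
    if isinstance(cohorts, pd.DataFrame):
        cohorts = [cohorts]
    brackets = [tuple(map(float, b)) for b in brackets]
    n_b = [0] * len(brackets)
    d_b = [0] * len(brackets)
    overall_n = overall_d = 0
    for df in cohorts:
        if label_col not in df.columns:
            raise EstimationError(f"cohort lacks the label column {label_col!r}")
        labels = df[label_col].astype(float)
        if labels.isna().any():
            raise EstimationError("labels contain missing values")
        labels = labels.astype(bool).to_numpy()
        ages = pd.to_numeric(df.get(age_col), errors="coerce").to_numpy(float) \
            if age_col in df.columns else np.full(len(df), np.nan)
        overall_n += len(df)
        overall_d += int(labels.sum())
        for i, (lo, hi) in enumerate(brackets):
            inside = (ages >= lo) & (ages < hi)
            n_b[i] += int(inside.sum())
            d_b[i] += int((inside & labels).sum())
    if overall_n == 0:
        raise EstimationError("no subjects provided")
    return AgeBracketPriors(brackets, n_b, d_b, overall_n, overall_d)


@dataclass
class ModelFeature:
    """A qualified feature inside a model: definition + frozen LRs + role."""

    definition: FeatureDefinition
    lr_pos: float
    lr_neg: float
    role: str

    def __post_init__(self):
        if self.role not in ("risk", "protective", "both"):
            raise ConfigurationError(
                f"feature {self.definition.name!r}: invalid role {self.role!r}"
            )

    @property
    def name(self) -> str:
        return self.definition.name

    def factor(self, present: bool) -> float:
        if present and self.role in ("risk", "both"):
            return self.lr_pos
        if not present and self.role in ("protective", "both"):
            return self.lr_neg
        return 1.0


@dataclass
class PrognosticModel:
    priors: AgeBracketPriors
    features: list  # of ModelFeature
    decision_cutoff: float = 0.5
    provenance: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list:
        return [f.name for f in self.features]

    # -- prediction ---------------------------------------------------------

    def posterior(self, age_of_onset, feature_vector) -> float:
        """Posterior probability for one subject.

        ``feature_vector`` is a mapping name->bool or a sequence aligned with
        ``self.features``.
        """
        if isinstance(feature_vector, dict):
            try:
                present = [bool(feature_vector[f.name]) for f in self.features]
            except KeyError as err:
                raise ContractError(
                    f"feature vector lacks {err.args[0]!r}"
                ) from None
        else:
            present = [bool(v) for v in feature_vector]
            if len(present) != len(self.features):
                raise ContractError(
                    "feature vector is not aligned with the model features"
                )
        prior = self.priors.lookup(age_of_onset)
        return _combine(prior, self.features, present)

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorized posteriors for a cohort DataFrame."""
        presence = binarize_cohort(df, [f.definition for f in self.features])
        ages = (
            pd.to_numeric(df["age_of_onset"], errors="coerce").to_numpy(float)
            if "age_of_onset" in df.columns
            else np.full(len(df), np.nan)
        )
        prior = self.priors.lookup_vector(ages)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            odds = prior / (1.0 - prior)
            for f in self.features:
                col = presence[f.name].to_numpy(bool)
                factor = np.where(
                    col,
                    f.lr_pos if f.role in ("risk", "both") else 1.0,
                    f.lr_neg if f.role in ("protective", "both") else 1.0,
                )
                odds = odds * factor
            post = odds / (1.0 + odds)
        post[np.isinf(odds)] = 1.0
        if np.isnan(odds).any():
            raise IndeterminateEvidenceError(
                "zero prior combined with an infinite likelihood ratio"
            )
        return post

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return predict_label(self.predict_proba(df), self.decision_cutoff)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "cogdecline-model",
            "version": 1,
            "priors": self.priors.to_dict(),
            "features": [
                {
                    "definition": f.definition.to_dict(),
                    "lr_pos": f.lr_pos,
                    "lr_neg": f.lr_neg,
                    "role": f.role,
                }
                for f in self.features
            ],
            "decision_cutoff": self.decision_cutoff,
            "provenance": self.provenance,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, raw: dict) -> "PrognosticModel":
        return cls(
            priors=AgeBracketPriors.from_dict(raw["priors"]),
            features=[
                ModelFeature(
                    definition=FeatureDefinition.from_dict(f["definition"]),
                    lr_pos=float(f["lr_pos"]),
                    lr_neg=float(f["lr_neg"]),
                    role=f["role"],
                )
                for f in raw["features"]
            ],
            decision_cutoff=float(raw.get("decision_cutoff", 0.5)),
            provenance=raw.get("provenance", {}),
        )

    @classmethod
    def load(cls, path) -> "PrognosticModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _combine(prior: float, features, present) -> float:
    if not (0.0 <= prior <= 1.0):
        raise ContractError("prior must lie in [0, 1]")
    if prior == 1.0:
        return 1.0
    factors = [f.factor(p) for f, p in zip(features, present)]
    if prior == 0.0:
        if any(math.isinf(x) for x in factors):
            raise IndeterminateEvidenceError(
                "zero prior with infinite likelihood ratio evidence"
            )
        return 0.0
    odds = prior / (1.0 - prior)
    for x in factors:
        odds *= x
    if math.isinf(odds):
        return 1.0
    return odds / (1.0 + odds)


def posterior_probability(model: PrognosticModel, age_of_onset, feature_vector):
    """Functional alias for :meth:`PrognosticModel.posterior`."""
    return model.posterior(age_of_onset, feature_vector)


def predict_label(posterior, cutoff: float = 0.5):
    """Positive iff posterior >= cutoff (inclusive: 50% is positive)."""
    arr = np.asarray(posterior, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ContractError("posteriors must lie in [0, 1]")
    out = arr >= cutoff
    return bool(out) if np.isscalar(posterior) else out


# ---------------------------------------------------------------------------
# Likelihood and backward elimination
# ---------------------------------------------------------------------------


def model_log_likelihood(
    model: PrognosticModel, df: pd.DataFrame, label_col: str = "decline"
) -> float:
    """Bernoulli log-likelihood of the observed outcome labels under the
    model posteriors, with probabilities clipped to [eps, 1-eps]."""
    y = df[label_col].astype(bool).to_numpy()
    p = np.clip(model.predict_proba(df), EPS, 1.0 - EPS)
    return float(np.sum(np.where(y, np.log(p), np.log1p(-p))))


def _without(model: PrognosticModel, name: str) -> PrognosticModel:
    return PrognosticModel(
        priors=model.priors,
        features=[f for f in model.features if f.name != name],
        decision_cutoff=model.decision_cutoff,
    )


def lrts_backward_elimination(
    model: PrognosticModel,
    df: pd.DataFrame,
    alpha: float = 0.05,
    label_col: str = "decline",
    reestimate: bool = False,
):
    """Sequentially drop features without a significant likelihood
    contribution.

    Per pass, every remaining feature's LRTS = 2 * (LL_full - LL_without) is
    computed; the smallest is removed if below the chi-squared(1) critical
    value, and the procedure repeats until all survivors are significant.
    Per-feature LRs are held fixed by default (naive Bayes LRs are marginal);
    ``reestimate=True`` refits them from the data after each removal.

    Returns ``(reduced_model, trace)`` where ``trace`` is a DataFrame of the
    per-pass statistics.  A model reduced to zero features is returned as a
    valid prior-only model.
    """
    critical = float(sps.chi2.ppf(1.0 - alpha, df=1))
    current = PrognosticModel(
        priors=model.priors,
        features=list(model.features),
        decision_cutoff=model.decision_cutoff,
        provenance=dict(model.provenance),
    )
    trace_rows = []
    step = 0
    while current.features:
        if reestimate:
            current = _refit_lrs(current, df, label_col)
        ll_full = model_log_likelihood(current, df, label_col)
        stats = {
            f.name: 2.0
            * (ll_full - model_log_likelihood(_without(current, f.name), df,
                                              label_col))
            for f in current.features
        }
        weakest = min(stats, key=stats.get)
        for name, lrts in stats.items():
            trace_rows.append(
                {
                    "step": step,
                    "feature": name,
                    "lrts": lrts,
                    "critical": critical,
                    "removed": name == weakest and stats[weakest] < critical,
                }
            )
        if stats[weakest] >= critical:
            break
        current = _without(current, weakest)
        step += 1
    trace = pd.DataFrame(
        trace_rows, columns=["step", "feature", "lrts", "critical", "removed"]
    )
    current.provenance.setdefault("elimination", {})["alpha"] = alpha
    return current, trace


def _refit_lrs(model, df, label_col):
    presence = binarize_cohort(df, [f.definition for f in model.features])
    decline = df[label_col].astype(bool).to_numpy()
    feats = []
    for f in model.features:
        st = likelihood_ratios(
            counts_from_vectors(presence[f.name].to_numpy(), decline)
        )
        feats.append(ModelFeature(f.definition, st.lr_pos, st.lr_neg, f.role))
    return PrognosticModel(model.priors, feats, model.decision_cutoff,
                           dict(model.provenance))


# ---------------------------------------------------------------------------
# Redundancy filtering
# ---------------------------------------------------------------------------


def jaccard_index(f1, f2) -> float:
    """|A intersection B| / |A union B| for boolean presence vectors; 0 by
    convention when both are all-absent."""
    f1 = np.asarray(f1, dtype=bool)
    f2 = np.asarray(f2, dtype=bool)
    union = int(np.sum(f1 | f2))
    if union == 0:
        return 0.0
    return float(np.sum(f1 & f2)) / union


def redundancy_filter(
    model: PrognosticModel,
    df: pd.DataFrame,
    threshold: float = 0.5,
    label_col: str = "decline",
):
    """Drop the weaker member of same-hypothesis feature pairs with Jaccard
    index strictly above ``threshold``.

    "Weaker" is the smaller single-feature LRTS contribution on ``df``; ties
    break on smaller |log LR+|, then lexicographic name.  Pairs in different
    hypothesis groups are never dropped.  Returns ``(filtered_model,
    dropped_names)``.
    """
    presence = binarize_cohort(df, [f.definition for f in model.features])
    ll_full = model_log_likelihood(model, df, label_col)
    contribution = {
        f.name: 2.0
        * (ll_full - model_log_likelihood(_without(model, f.name), df,
                                          label_col))
        for f in model.features
    }

    def sort_key(feat: ModelFeature):
        lr = feat.lr_pos
        loglr = abs(math.log(lr)) if lr > 0 and math.isfinite(lr) else math.inf
        return (contribution[feat.name], loglr, [-ord(c) for c in feat.name])

    dropped: list = []
    feats = list(model.features)
    changed = True
    while changed:
        changed = False
        for i, fi in enumerate(feats):
            for fj in feats[i + 1 :]:
                gi = fi.definition.hypothesis_group
                gj = fj.definition.hypothesis_group
                if gi is None or gi != gj:
                    continue
                j = jaccard_index(presence[fi.name], presence[fj.name])
                if j > threshold:
                    loser = min((fi, fj), key=sort_key)
                    feats = [f for f in feats if f.name != loser.name]
                    dropped.append(loser.name)
                    changed = True
                    break
            if changed:
                break
    return (
        PrognosticModel(model.priors, feats, model.decision_cutoff,
                        dict(model.provenance)),
        dropped,
    )


# ---------------------------------------------------------------------------
# Full fitting pipeline
# ---------------------------------------------------------------------------


def fit_model(
    df: pd.DataFrame,
    defs: list,
    brackets=DEFAULT_BRACKETS,
    label_col: str = "decline",
    alpha: float = 0.05,
    jaccard_threshold: float = 0.5,
    eliminate: bool = True,
    decision_cutoff: float = 0.5,
):
    """Fit the full pipeline on a labeled cohort.

    Steps: binarize and estimate per-feature LRs; keep features qualifying as
    risk/protective/both; drop redundant same-hypothesis features (Jaccard);
    backward-eliminate by LRTS using the whole-dataset prior (bracket priors
    would leak the age structure into feature selection); finally attach the
    age-bracket priors estimated from the cohort.

    Returns ``(model, trace)`` with the per-feature statistics and the
    elimination trace in ``trace``.
    """
    presence = binarize_cohort(df, defs)
    decline = df[label_col].astype(bool).to_numpy()
    if decline.all() or not decline.any():
        raise EstimationError("cohort must contain both outcome classes")

    qualified = []
    feature_rows = []
    for d in defs:
        st = likelihood_ratios(
            counts_from_vectors(presence[d.name].to_numpy(), decline),
            name=d.name,
        )
        role = qualify_feature(st)
        feature_rows.append(
            {"feature": d.name, "lr_pos": st.lr_pos, "lr_neg": st.lr_neg,
             "proportion": st.presence_proportion, "fisher_p": st.fisher_p,
             "role": role}
        )
        if role != "rejected":
            qualified.append(ModelFeature(d, st.lr_pos, st.lr_neg, role))

    priors = estimate_priors(df, brackets=brackets, label_col=label_col)
    flat_priors = AgeBracketPriors(
        brackets=[],
        n_per_bracket=[],
        decliners_per_bracket=[],
        overall_n=priors.overall_n,
        overall_decliners=priors.overall_decliners,
    )
    selection_model = PrognosticModel(flat_priors, qualified, decision_cutoff)
    selection_model, dropped = redundancy_filter(
        selection_model, df, threshold=jaccard_threshold, label_col=label_col
    )
    if eliminate:
        selection_model, elim_trace = lrts_backward_elimination(
            selection_model, df, alpha=alpha, label_col=label_col
        )
    else:
        elim_trace = pd.DataFrame(
            columns=["step", "feature", "lrts", "critical", "removed"]
        )
    final = PrognosticModel(
        priors=priors,
        features=selection_model.features,
        decision_cutoff=decision_cutoff,
        provenance={
            "n_subjects": int(len(df)),
            "jaccard_dropped": dropped,
            "alpha": alpha,
        },
    )
    return final, {"features": pd.DataFrame(feature_rows),
                   "elimination": elim_trace,
                   "jaccard_dropped": dropped}


def published_model() -> PrognosticModel:
    """The packaged four-question model (age-bracket priors + history of
    stroke, fainting in the past six months, vocalization during dreams)."""
    ref = resources.files("cogdecline.data") / "published_model.json"
    with ref.open("r", encoding="utf-8") as fh:
        return PrognosticModel.from_dict(json.load(fh))
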