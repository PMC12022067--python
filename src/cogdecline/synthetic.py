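"""Synthetic de novo PD cohorts with known generative structure.

The access-controlled study data are emulated by a generator whose stated
world matches the published summary statistics: age-of-onset brackets with
bracketed decline probabilities, per-feature class-conditional presence
(sensitivity among decliners, 1 - specificity among non-decliners,
independent given outcome — the naive Bayes assumption), MoCA trajectories
realizing the assigned stable/early/late/fluctuation pattern, and MCAR
item-level missingness.

Because the generative (sens, spec) are known, analytic oracles are exact:
:func:`implied_feature_stats` gives the population likelihood ratios and
presence proportions, and :func:`expected_model_auc` the exact AUC of a
model's posterior score under the generative distribution by enumerating
all feature-pattern-by-bracket combinations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .features import FeatureDefinition
from .model import PrognosticModel

__all__ = [
    "FeatureSpec",
    "TrajectoryMix",
    "SyntheticConfig",
    "study_like_config",
    "generate_cohort",
    "implied_feature_stats",
    "ImpliedFeatureStats",
    "expected_model_auc",
    "COMBINED_BRACKET_COUNTS",
    "TRAINING_BRACKET_COUNTS",
    "VALIDATION_BRACKET_COUNTS",
    "load_config",
    "save_config",
]

# Published per-bracket (subjects, decliners) counts of future cognitive
# decline by age of onset; decliner counts recovered from n x prior.
TRAINING_BRACKET_COUNTS = {
    (30.0, 40.0): (4, 2),
    (40.0, 45.0): (6, 2),
    (45.0, 50.0): (25, 3),
    (50.0, 55.0): (24, 3),
    (55.0, 60.0): (31, 5),
    (60.0, 65.0): (37, 10),
    (65.0, 70.0): (34, 15),
    (70.0, 75.0): (13, 4),
    (75.0, 100.0): (8, 5),
}
VALIDATION_BRACKET_COUNTS = {
    (30.0, 40.0): (5, 1),
    (40.0, 45.0): (1, 0),
    (45.0, 50.0): (6, 0),
    (50.0, 55.0): (3, 0),
    (55.0, 60.0): (10, 3),
    (60.0, 65.0): (6, 0),
    (65.0, 70.0): (6, 1),
    (70.0, 75.0): (6, 2),
    (75.0, 100.0): (3, 2),
}
COMBINED_BRACKET_COUNTS = {
    b: (TRAINING_BRACKET_COUNTS[b][0] + VALIDATION_BRACKET_COUNTS[b][0],
        TRAINING_BRACKET_COUNTS[b][1] + VALIDATION_BRACKET_COUNTS[b][1])
    for b in TRAINING_BRACKET_COUNTS
}


def _check_prob(name, p):
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class FeatureSpec:
    """A generated binary feature: class-conditional presence rates.

    ``kind='risk'`` features must satisfy sensitivity > 1 - specificity
    (implied LR+ > 1); ``kind='noise'`` features are exempt (used for null
    calibration), ``kind='protective'`` requires LR+ < 1.
    """

    name: str
    sensitivity: float
    specificity: float
    kind: str = "risk"

    def __post_init__(self):
        _check_prob(f"feature {self.name!r} sensitivity", self.sensitivity)
        _check_prob(f"feature {self.name!r} specificity", self.specificity)
        if self.kind == "risk" and not (
            self.sensitivity > 1.0 - self.specificity
        ):
            raise ConfigurationError(
                f"risk feature {self.name!r} needs sensitivity > 1 - "
                "specificity (implied LR+ > 1)"
            )
        if self.kind == "protective" and not (
            self.sensitivity < 1.0 - self.specificity
        ):
            raise ConfigurationError(
                f"protective feature {self.name!r} needs implied LR+ < 1"
            )
        if self.kind not in ("risk", "protective", "noise"):
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class TrajectoryMix:
    """Split of MoCA trajectory patterns among decliners.

    Every decliner realizes early, late or fluctuation (a year-2 drop of
    >= 3 points makes fluctuators decliners under the and/or label);
    non-decliners are stable.
    """

    early: float = 0.37
    late: float = 0.33
    fluctuation: float = 0.30

    def __post_init__(self):
        for name in ("early", "late", "fluctuation"):
            _check_prob(f"trajectory_mix.{name}", getattr(self, name))
        if abs(self.early + self.late + self.fluctuation - 1.0) > 1e-9:
            raise ConfigurationError(
                "trajectory_mix probabilities for decliners must sum to 1"
            )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a synthetic cohort (the stated world)."""

    n_subjects: int
    bracket_rates: dict  # (lo, hi) -> decline probability
    age_weights: dict  # (lo, hi) -> sampling weight
    feature_specs: tuple = ()
    trajectory_mix: TrajectoryMix = field(default_factory=TrajectoryMix)
    moca_baseline_mean: float = 27.2
    moca_baseline_sd: float = 2.1
    missing_rate: float = 0.02
    missing_age_rate: float = 0.0
    p_male: float = 0.64
    seed: int = 0
    # Optional pairwise-copula hook: (feature_a, feature_b, agreement) makes
    # feature_b copy feature_a with the given probability (else an
    # independent draw), to exercise the redundancy filter.  Default off;
    # the analytic oracles assume independence and ignore it.
    pairwise_dependence: tuple = ()

    def __post_init__(self):
        if int(self.n_subjects) != self.n_subjects or self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be a nonnegative integer")
        if set(self.bracket_rates) != set(self.age_weights):
            raise ConfigurationError(
                "bracket_rates and age_weights must share the same brackets"
            )
        spans = sorted(self.bracket_rates)
        if not spans:
            raise ConfigurationError("at least one age bracket is required")
        if spans[0][0] != 30.0 or spans[-1][1] != 100.0:
            raise ConfigurationError("age brackets must partition [30, 100)")
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if hi1 != lo2:
                raise ConfigurationError("age brackets must partition [30, 100)")
        for (lo, hi), rate in self.bracket_rates.items():
            if not lo < hi:
                raise ConfigurationError("bracket bounds must increase")
            _check_prob(f"bracket_rates[{lo}-{hi}]", rate)
        for w in self.age_weights.values():
            if w < 0:
                raise ConfigurationError("age weights must be nonnegative")
        if sum(self.age_weights.values()) <= 0:
            raise ConfigurationError("age weights must sum to a positive value")
        for p, name in (
            (self.missing_rate, "missing_rate"),
            (self.missing_age_rate, "missing_age_rate"),
            (self.p_male, "p_male"),
        ):
            _check_prob(name, p)
        names = [f.name for f in self.feature_specs]
        if len(names) != len(set(names)):
            raise ConfigurationError("feature names must be unique")
        for a, b, agree in self.pairwise_dependence:
            if a not in names or b not in names:
                raise ConfigurationError(
                    f"pairwise dependence names unknown feature ({a!r}, {b!r})"
                )
            _check_prob("pairwise agreement", agree)

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    def feature_definitions(self, groups: dict | None = None) -> list:
        """Flag-style feature definitions over the generated 0/1 columns."""
        groups = groups or {}
        return [
            FeatureDefinition(
                name=f.name,
                source=f.name,
                comparator="flag",
                hypothesis_sign=+1,
                hypothesis_group=groups.get(f.name),
                description=f"synthetic binary feature {f.name!r}",
            )
            for f in self.feature_specs
        ]

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_subjects": int(self.n_subjects),
            "brackets": [
                {"lo": lo, "hi": hi, "rate": self.bracket_rates[(lo, hi)],
                 "weight": self.age_weights[(lo, hi)]}
                for lo, hi in sorted(self.bracket_rates)
            ],
            "features": [dataclasses.asdict(f) for f in self.feature_specs],
            "trajectory_mix": dataclasses.asdict(self.trajectory_mix),
            "moca_baseline_mean": self.moca_baseline_mean,
            "moca_baseline_sd": self.moca_baseline_sd,
            "missing_rate": self.missing_rate,
            "missing_age_rate": self.missing_age_rate,
            "p_male": self.p_male,
            "seed": int(self.seed),
            "pairwise_dependence": [list(t) for t in self.pairwise_dependence],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        return cls(
            n_subjects=raw["n_subjects"],
            bracket_rates={
                (float(b["lo"]), float(b["hi"])): float(b["rate"])
                for b in raw["brackets"]
            },
            age_weights={
                (float(b["lo"]), float(b["hi"])): float(b["weight"])
                for b in raw["brackets"]
            },
            feature_specs=tuple(
                FeatureSpec(**f) for f in raw.get("features", [])
            ),
            trajectory_mix=TrajectoryMix(**raw.get("trajectory_mix", {})),
            moca_baseline_mean=raw.get("moca_baseline_mean", 27.2),
            moca_baseline_sd=raw.get("moca_baseline_sd", 2.1),
            missing_rate=raw.get("missing_rate", 0.02),
            missing_age_rate=raw.get("missing_age_rate", 0.0),
            p_male=raw.get("p_male", 0.64),
            seed=raw.get("seed", 0),
            pairwise_dependence=tuple(
                tuple(t) for t in raw.get("pairwise_dependence", [])
            ),
        )


def load_config(path) -> SyntheticConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return SyntheticConfig.from_dict(yaml.safe_load(fh))


def save_config(config: SyntheticConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def study_like_config(
    n_subjects: int = 186, seed: int = 0, **overrides
) -> SyntheticConfig:
    """The default stated world: combined-table age priors and the three
    four-question features at their published-table operating points
    (fainting sens 2/49, spec 135/137 — LR+ 2.80, LR- 0.97, presence 0.02;
    dream vocalization sens 27/49, spec 109/137 — LR+ 2.70, LR- 0.56;
    stroke sens 3/49, spec 1 — infinite implied LR+).

    Columns are named after the source variables of the packaged feature
    battery (``stroke``, ``scopa_16``, ``rbdsq_6_1``), so the published
    four-question model scores these cohorts directly.
    """
    kwargs = dict(
        n_subjects=n_subjects,
        bracket_rates={b: d / n for b, (n, d) in COMBINED_BRACKET_COUNTS.items()},
        age_weights={b: float(n) for b, (n, _) in COMBINED_BRACKET_COUNTS.items()},
        feature_specs=(
            FeatureSpec("stroke", 3 / 49, 1.0),
            FeatureSpec("scopa_16", 2 / 49, 135 / 137),
            FeatureSpec("rbdsq_6_1", 27 / 49, 109 / 137),
        ),
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a cohort from the generative model, reproducibly from the seed.

    Columns: subject metadata, MoCA baseline/year-2/year-4 totals, one 0/1
    column per feature (NaN where masked missing), plus the simulation truth
    ``sim_decline`` and ``sim_pattern``.  Provenance (config + seed) is
    attached as ``df.attrs['provenance']``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.n_subjects)
    spans = sorted(config.bracket_rates)
    weights = np.array([config.age_weights[b] for b in spans], dtype=float)
    weights = weights / weights.sum()
    rates = np.array([config.bracket_rates[b] for b in spans], dtype=float)
    lo = np.array([b[0] for b in spans])
    hi = np.array([b[1] for b in spans])

    bracket = rng.choice(len(spans), size=n, p=weights)
    age = lo[bracket] + rng.random(n) * (hi[bracket] - lo[bracket])
    decline = rng.random(n) < rates[bracket]

    mix = config.trajectory_mix
    pattern = np.full(n, "stable", dtype=object)
    u = rng.random(n)
    pattern[decline & (u < mix.early)] = "early_decline"
    pattern[decline & (u >= mix.early) & (u < mix.early + mix.late)] = (
        "late_decline"
    )
    pattern[decline & (u >= mix.early + mix.late)] = "fluctuation"

    base = np.clip(
        np.rint(rng.normal(config.moca_baseline_mean, config.moca_baseline_sd,
                           n)),
        0, 30,
    ).astype(int)
    # A decline pattern needs headroom for a >= 3-point drop; floor those
    # baselines at 3 (immaterial at realistic MoCA means, keeps the label
    # consistency invariant exact).
    base[pattern != "stable"] = np.maximum(base[pattern != "stable"], 3)

    def big_drop(size):
        return 3 + (rng.geometric(0.5, size) - 1)

    def small_delta(size):
        return rng.integers(-2, 3, size)

    y2 = np.empty(n, dtype=int)
    y4 = np.empty(n, dtype=int)
    for pat in ("stable", "early_decline", "late_decline", "fluctuation"):
        m = pattern == pat
        k = int(m.sum())
        if k == 0:
            continue
        b = base[m]
        if pat == "early_decline":
            y2[m] = b - np.minimum(big_drop(k), b)
            y4[m] = b - np.minimum(big_drop(k), b)
        elif pat == "late_decline":
            y2[m] = np.clip(b - small_delta(k), 0, 30)
            y4[m] = b - np.minimum(big_drop(k), b)
        elif pat == "fluctuation":
            y2[m] = b - np.minimum(big_drop(k), b)
            y4[m] = np.clip(b - small_delta(k), 0, 30)
        else:
            y2[m] = np.clip(b - small_delta(k), 0, 30)
            y4[m] = np.clip(b - small_delta(k), 0, 30)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "sex": np.where(rng.random(n) < config.p_male, "male", "female"),
            "education_years": np.clip(
                np.rint(rng.normal(15.4, 2.9, n)), 5, 24
            ).astype(int),
            "age_of_onset": np.round(age, 2),
            "moca": base,
            "moca_y2": y2,
            "moca_y4": y4,
        }
    )
    if config.missing_age_rate > 0:
        mask = rng.random(n) < config.missing_age_rate
        df.loc[mask, "age_of_onset"] = np.nan

    values = {}
    for f in config.feature_specs:
        p = np.where(decline, f.sensitivity, 1.0 - f.specificity)
        values[f.name] = (rng.random(n) < p).astype(float)
    for a, b_name, agree in config.pairwise_dependence:
        copy = rng.random(n) < agree
        values[b_name] = np.where(copy, values[a], values[b_name])
    for f in config.feature_specs:
        col = values[f.name]
        if config.missing_rate > 0:
            col = col.copy()
            col[rng.random(n) < config.missing_rate] = np.nan
        df[f.name] = col

    df["sim_decline"] = decline.astype(int)
    df["sim_pattern"] = pattern
    df.attrs["provenance"] = {"config": config.to_dict(), "seed": int(config.seed)}
    return df


# ---------------------------------------------------------------------------
# Analytic oracles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImpliedFeatureStats:
    """Population diagnostic statistics implied by a FeatureSpec."""

    name: str
    lr_pos: float
    lr_neg: float
    expected_presence: float
    prevalence: float


def implied_feature_stats(config: SyntheticConfig) -> list:
    """Exact LR+, LR- and expected observed presence per feature.

    LR+ = sens / (1 - spec) (infinite at spec = 1 with sens > 0), LR- =
    (1 - sens) / spec.  Expected presence mixes over brackets,
    sum_k w_k [r_k sens + (1 - r_k)(1 - spec)], scaled by (1 - missing_rate)
    because masked items binarize to absent.  Assumes feature independence
    (the pairwise-dependence hook is ignored).
    """
    weights = np.array(
        [config.age_weights[b] for b in sorted(config.bracket_rates)],
        dtype=float,
    )
    weights = weights / weights.sum()
    rates = np.array(
        [config.bracket_rates[b] for b in sorted(config.bracket_rates)],
        dtype=float,
    )
    prevalence = float(np.sum(weights * rates))
    out = []
    for f in config.feature_specs:
        fp = 1.0 - f.specificity
        if fp == 0.0:
            lr_pos = float("inf") if f.sensitivity > 0 else float("nan")
        else:
            lr_pos = f.sensitivity / fp
        lr_neg = (
            (1.0 - f.sensitivity) / f.specificity
            if f.specificity > 0
            else (float("inf") if f.sensitivity < 1 else float("nan"))
        )
        presence = float(
            np.sum(weights * (rates * f.sensitivity + (1.0 - rates) * fp))
        ) * (1.0 - config.missing_rate)
        out.append(
            ImpliedFeatureStats(f.name, lr_pos, lr_neg, presence, prevalence)
        )
    return out


def expected_model_auc(
    config: SyntheticConfig, model: PrognosticModel, max_features: int = 20
) -> float:
    """Exact AUC of the model's posterior score under the generative law.

    Enumerates every feature pattern x age bracket with its class-
    conditional probability (observed presence folds in MCAR masking:
    sens (1 - miss) among decliners, (1 - spec)(1 - miss) among
    non-decliners) and scores it with the model; ties count 1/2.
    """
    spec_by_name = {f.name: f for f in config.feature_specs}

    def spec_for(feature):
        # Generated columns are named after the FeatureSpec; a model feature
        # binds to its source column (flag/threshold on a 0/1 column), so
        # match on the source first, then on the feature name.
        key = feature.definition.source
        if key not in spec_by_name:
            key = feature.name
        return spec_by_name.get(key)

    missing = [f.name for f in model.features if spec_for(f) is None]
    if missing:
        raise ConfigurationError(
            f"model features {missing} not generated by this config"
        )
    m = len(model.features)
    spans = sorted(config.bracket_rates)
    size = len(spans) * (2 ** m)
    if m > max_features:
        raise ConfigurationError(
            f"enumeration of {size} pattern-bracket combinations refused "
            f"({m} features > {max_features})"
        )
    weights = np.array([config.age_weights[b] for b in spans], dtype=float)
    weights = weights / weights.sum()
    rates = np.array([config.bracket_rates[b] for b in spans], dtype=float)

    keep = 1.0 - config.missing_rate
    p1 = np.array([spec_for(f).sensitivity * keep for f in model.features])
    p0 = np.array(
        [(1.0 - spec_for(f).specificity) * keep for f in model.features]
    )

    scores, mass1, mass0 = [], [], []
    patterns = (
        (np.arange(2 ** m)[:, None] >> np.arange(m)[None, :]) & 1
    ).astype(bool) if m else np.zeros((1, 0), dtype=bool)
    for k, (lo, hi) in enumerate(spans):
        age_mid = (lo + hi) / 2.0
        for x in patterns:
            pr1 = float(np.prod(np.where(x, p1, 1.0 - p1)))
            pr0 = float(np.prod(np.where(x, p0, 1.0 - p0)))
            scores.append(model.posterior(age_mid, list(x)))
            mass1.append(weights[k] * rates[k] * pr1)
            mass0.append(weights[k] * (1.0 - rates[k]) * pr0)
    scores = np.asarray(scores)
    mass1 = np.asarray(mass1)
    mass0 = np.asarray(mass0)
    total1, total0 = mass1.sum(), mass0.sum()
    if total1 == 0 or total0 == 0:
        raise ConfigurationError(
            "generative law puts zero mass on one outcome class"
        )
    mass1, mass0 = mass1 / total1, mass0 / total0
    order = np.argsort(scores)
    scores, mass1, mass0 = scores[order], mass1[order], mass0[order]
    auc = 0.0
    cum0 = 0.0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tie1 = mass1[i:j].sum()
        tie0 = mass0[i:j].sum()
        auc += tie1 * (cum0 + 0.5 * tie0)
        cum0 += tie0
        i = j
    return float(auc)
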