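"""Derived clinical scores and binarization of baseline variables.

The prognostic pipeline works on presence/absence features.  This module
derives the compound motor and cognitive scores (lateralized MDS-UPDRS III
sub-scores, PIGD/tremor phenotype, MoCA domain sub-scores) and converts every
variable into a binary feature through a :class:`FeatureDefinition` — a named
cutoff rule with a direction hypothesis.

Conventions
-----------
* Comparators are strict ("higher than 5" means > 5, "lower than 31" means
  < 31); equality at the cutoff is *absent*.
* A missing source value, or a derived score with any missing constituent
  item, binarizes to *absent* (missing values are treated as absent
  symptoms).  Partial sums are never taken: they would silently shift the
  cutoff semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

__all__ = [
    "FeatureDefinition",
    "lateralized_subscores",
    "pigd_tremor_phenotype",
    "moca_domain_subscores",
    "derive_scores",
    "binarize_record",
    "binarize_cohort",
    "load_feature_definitions",
    "dump_feature_definitions",
    "default_feature_definitions",
]

COMPARATORS = ("gt", "lt", "eq", "flag")

# ---------------------------------------------------------------------------
# MDS-UPDRS III item groupings (by side) for the lateralized sub-scores.
# ---------------------------------------------------------------------------

RIGIDITY_ITEMS = {
    "right": ["updrs3_rigidity_rue", "updrs3_rigidity_rle"],
    "left": ["updrs3_rigidity_lue", "updrs3_rigidity_lle"],
}
AKINESIA_ITEMS = {
    "right": [
        "updrs3_finger_tapping_r",
        "updrs3_hand_movements_r",
        "updrs3_pronation_supination_r",
        "updrs3_toe_tapping_r",
        "updrs3_leg_agility_r",
    ],
    "left": [
        "updrs3_finger_tapping_l",
        "updrs3_hand_movements_l",
        "updrs3_pronation_supination_l",
        "updrs3_toe_tapping_l",
        "updrs3_leg_agility_l",
    ],
}
LATERAL_TREMOR_ITEMS = {
    "right": [
        "updrs3_postural_tremor_r",
        "updrs3_kinetic_tremor_r",
        "updrs3_rest_tremor_rue",
        "updrs3_rest_tremor_rle",
    ],
    "left": [
        "updrs3_postural_tremor_l",
        "updrs3_kinetic_tremor_l",
        "updrs3_rest_tremor_lue",
        "updrs3_rest_tremor_lle",
    ],
}

PIGD_ITEMS = [
    "updrs3_arising_from_chair",
    "updrs3_gait",
    "updrs3_freezing_of_gait",
    "updrs3_postural_stability",
    "updrs3_posture",
]
# Rest tremor of lip/jaw and all four limbs plus postural and kinetic tremor
# of both arms, averaged (phenotype tremor score).
TREMOR_SCORE_ITEMS = [
    "updrs3_rest_tremor_lipjaw",
    "updrs3_rest_tremor_rue",
    "updrs3_rest_tremor_lue",
    "updrs3_rest_tremor_rle",
    "updrs3_rest_tremor_lle",
    "updrs3_postural_tremor_r",
    "updrs3_postural_tremor_l",
    "updrs3_kinetic_tremor_r",
    "updrs3_kinetic_tremor_l",
]

# MoCA v1.0 domain regrouping (item -> points).
MOCA_DOMAINS = {
    "visuospatial_executive": [
        "moca_trail",
        "moca_cube",
        "moca_clock_contour",
        "moca_clock_numbers",
        "moca_clock_hands",
    ],
    "naming": ["moca_naming_lion", "moca_naming_rhino", "moca_naming_camel"],
    "attention": [
        "moca_digits_forward",
        "moca_digits_backward",
        "moca_vigilance",
        "moca_serial7",
    ],
    "language": ["moca_repetition", "moca_fluency"],
    "abstraction": ["moca_abstraction"],
    "delayed_recall": ["moca_recall"],
    "orientation": ["moca_orientation"],
}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return value is pd.NA


def _sum_items(items: Mapping[str, float], names: list[str]):
    """Sum of the named items; ``None`` if any constituent is missing."""
    total = 0.0
    for name in names:
        value = items.get(name)
        if _is_missing(value):
            return None
        total += float(value)
    return total


def lateralized_subscores(updrs3_items: Mapping[str, float]) -> dict:
    """Lateralized MDS-UPDRS III sub-scores.

    Rigidity per side sums the upper- and lower-limb rigidity items; akinesia
    per side sums finger tapping, hand movements, pronation-supination, toe
    tapping and leg agility; tremor per side sums postural, kinetic and rest
    tremor amplitude of the hand and leg.  The unilateral score averages the
    left and right sums.  Any missing constituent item makes the affected
    sub-score ``None`` (it then binarizes as an absent symptom).
    """
    out: dict = {}
    for domain, groups in (
        ("rigidity", RIGIDITY_ITEMS),
        ("akinesia", AKINESIA_ITEMS),
        ("tremor", LATERAL_TREMOR_ITEMS),
    ):
        for side in ("left", "right"):
            out[f"{domain}_{side}"] = _sum_items(updrs3_items, groups[side])
        left, right = out[f"{domain}_left"], out[f"{domain}_right"]
        out[f"{domain}_unilateral"] = (
            None if left is None or right is None else (left + right) / 2.0
        )
    return out


def pigd_tremor_phenotype(updrs_items: Mapping[str, float]):
    """PIGD and tremor mean scores plus the motor phenotype.

    Phenotype rule: tremor/PIGD ratio <= 1.0 -> ``"pigd"``; ratio >= 1.5 ->
    ``"tremor_dominant"``; strictly between -> ``"indeterminate"``.  With a
    zero PIGD score the ratio is infinite (tremor-dominant) unless the tremor
    score is also zero, in which case the phenotype is indeterminate by
    convention.
    """
    pigd = _sum_items(updrs_items, PIGD_ITEMS)
    tremor = _sum_items(updrs_items, TREMOR_SCORE_ITEMS)
    pigd = None if pigd is None else pigd / len(PIGD_ITEMS)
    tremor = None if tremor is None else tremor / len(TREMOR_SCORE_ITEMS)
    if pigd is None or tremor is None:
        return pigd, tremor, None
    if pigd == 0.0:
        phenotype = "indeterminate" if tremor == 0.0 else "tremor_dominant"
    else:
        ratio = tremor / pigd
        if ratio <= 1.0:
            phenotype = "pigd"
        elif ratio >= 1.5:
            phenotype = "tremor_dominant"
        else:
            phenotype = "indeterminate"
    return pigd, tremor, phenotype


def moca_domain_subscores(moca_items: Mapping[str, float]) -> dict:
    """Seven MoCA domain sums (visuospatial/executive, naming, attention,
    language, abstraction, delayed recall, orientation)."""
    for name in moca_items:
        if not any(name in items for items in MOCA_DOMAINS.values()):
            raise ConfigurationError(f"unknown MoCA item {name!r}")
    return {
        domain: _sum_items(moca_items, names)
        for domain, names in MOCA_DOMAINS.items()
    }


# ---------------------------------------------------------------------------
# Feature definitions
# ---------------------------------------------------------------------------


@dataclass
class FeatureDefinition:
    """A named binary predictor: source variable, cutoff rule, direction.

    ``comparator`` is one of ``gt``/``lt``/``eq``/``flag``; ``flag`` reads a
    boolean source directly and carries no cutoff.  ``sex_specific_cutoffs``
    (e.g. UPSIT < 31 for females, < 30 for males) overrides ``cutoff`` based
    on the record's sex.  ``hypothesis_sign`` is +1 when a higher source value
    is hypothesized to carry more risk, -1 otherwise; ``hypothesis_group``
    names the clinical hypothesis for the redundancy filter.  ``role`` is
    assigned from the estimated likelihood ratios, not here.
    """

    name: str
    source: str
    comparator: str
    cutoff: float | None = None
    sex_specific_cutoffs: dict | None = None
    hypothesis_sign: int = 1
    hypothesis_group: str | None = None
    description: str = ""
    role: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.comparator not in COMPARATORS:
            raise ConfigurationError(
                f"feature {self.name!r}: unknown comparator {self.comparator!r}"
            )
        if self.comparator == "flag":
            if self.cutoff is not None:
                raise ConfigurationError(
                    f"feature {self.name!r}: flag comparator takes no cutoff"
                )
        elif self.sex_specific_cutoffs is None:
            if self.cutoff is None or not math.isfinite(float(self.cutoff)):
                raise ConfigurationError(
                    f"feature {self.name!r}: cutoff must be finite"
                )
        if self.hypothesis_sign not in (+1, -1):
            raise ConfigurationError(
                f"feature {self.name!r}: hypothesis_sign must be +1 or -1"
            )

    def resolve_cutoff(self, sex: str | None):
        if self.sex_specific_cutoffs:
            if sex in self.sex_specific_cutoffs:
                return self.sex_specific_cutoffs[sex]
            raise ConfigurationError(
                f"feature {self.name!r}: no cutoff for sex {sex!r}"
            )
        return self.cutoff

    def is_present(self, value, sex: str | None = None) -> bool:
        """Apply the cutoff rule to one source value (missing -> absent)."""
        if _is_missing(value):
            return False
        if self.comparator == "flag":
            return bool(value)
        cutoff = self.resolve_cutoff(sex)
        if self.comparator == "gt":
            return float(value) > float(cutoff)
        if self.comparator == "lt":
            return float(value) < float(cutoff)
        return float(value) == float(cutoff)

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "source": self.source,
            "comparator": self.comparator,
            "hypothesis_sign": self.hypothesis_sign,
        }
        if self.comparator != "flag":
            if self.sex_specific_cutoffs:
                out["sex_specific_cutoffs"] = dict(self.sex_specific_cutoffs)
            else:
                out["cutoff"] = self.cutoff
        for key in ("hypothesis_group", "description", "role"):
            value = getattr(self, key)
            if value:
                out[key] = value
        if self.metadata:
            out["metadata"] = dict(self.metadata)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "FeatureDefinition":
        return cls(
            name=raw["name"],
            source=raw["source"],
            comparator=raw["comparator"],
            cutoff=raw.get("cutoff"),
            sex_specific_cutoffs=raw.get("sex_specific_cutoffs"),
            hypothesis_sign=int(raw.get("hypothesis_sign", 1)),
            hypothesis_group=raw.get("hypothesis_group"),
            description=raw.get("description", ""),
            role=raw.get("role"),
            metadata=raw.get("metadata", {}),
        )


def load_feature_definitions(path_or_stream) -> list[FeatureDefinition]:
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return [FeatureDefinition.from_dict(item) for item in raw["features"]]


def dump_feature_definitions(defs: list[FeatureDefinition], path) -> None:
    payload = {"version": 1, "features": [d.to_dict() for d in defs]}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def default_feature_definitions() -> list[FeatureDefinition]:
    """The packaged battery of 22 baseline cutoff features."""
    ref = resources.files("cogdecline.data") / "feature_definitions.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return load_feature_definitions(fh)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


def derive_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived-score columns (lateralized sub-scores, phenotype, MoCA
    domains) where the constituent item columns exist.  Missing constituents
    yield NaN in the derived column."""
    out = df.copy()
    rows = df.to_dict("records")
    if set(RIGIDITY_ITEMS["right"]).issubset(df.columns):
        derived = [lateralized_subscores(row) for row in rows]
        for key in derived[0] if derived else []:
            out[f"updrs3_{key}"] = [
                np.nan if d[key] is None else d[key] for d in derived
            ]
        if derived:
            out["right_rigidity"] = out["updrs3_rigidity_right"]
            out["left_rigidity"] = out["updrs3_rigidity_left"]
    if set(PIGD_ITEMS).issubset(df.columns):
        trip = [pigd_tremor_phenotype(row) for row in rows]
        out["pigd_score"] = [np.nan if t[0] is None else t[0] for t in trip]
        out["tremor_score"] = [np.nan if t[1] is None else t[1] for t in trip]
        out["motor_phenotype"] = [t[2] for t in trip]
    moca_cols = [c for cols in MOCA_DOMAINS.values() for c in cols]
    if set(MOCA_DOMAINS["visuospatial_executive"]).issubset(df.columns):
        present = [c for c in moca_cols if c in df.columns]
        for domain, names in MOCA_DOMAINS.items():
            if set(names).issubset(df.columns):
                sums = [_sum_items(row, names) for row in rows]
                out[f"moca_{domain}"] = [
                    np.nan if s is None else s for s in sums
                ]
        del present
    return out


def binarize_record(
    values: Mapping[str, object], defs: list[FeatureDefinition]
) -> np.ndarray:
    """Binary feature vector for one subject (mapping of variable -> value).

    Total: always returns one boolean per definition; a missing source value
    maps to absent.  A definition whose source is not even a key of the
    mapping is a configuration error (schema mismatch, not missingness).
    """
    sex = values.get("sex")
    out = np.zeros(len(defs), dtype=bool)
    for i, d in enumerate(defs):
        if d.source not in values:
            raise ConfigurationError(
                f"feature {d.name!r}: source variable {d.source!r} absent "
                "from the record schema"
            )
        out[i] = d.is_present(values[d.source], sex=sex)
    return out


def binarize_cohort(
    df: pd.DataFrame, defs: list[FeatureDefinition], derive: bool = True
) -> pd.DataFrame:
    """Presence/absence matrix (one boolean column per feature definition).

    Derived scores are computed first so definitions can reference them.
    Vectorized over subjects; missing values are absent symptoms.
    """
    data = derive_scores(df) if derive else df
    out = pd.DataFrame(index=data.index)
    sex = data["sex"] if "sex" in data.columns else None
    for d in defs:
        if d.source not in data.columns:
            raise ConfigurationError(
                f"feature {d.name!r}: source variable {d.source!r} absent "
                "from the cohort schema"
            )
        col = pd.to_numeric(data[d.source], errors="coerce")
        if d.comparator == "flag":
            present = col.fillna(0).astype(float) != 0.0
        else:
            if d.sex_specific_cutoffs:
                if sex is None:
                    raise ConfigurationError(
                        f"feature {d.name!r}: sex-specific cutoffs require a "
                        "'sex' column"
                    )
                cut = sex.map(d.sex_specific_cutoffs).astype(float)
                if cut.isna().any():
                    bad = sex[cut.isna()].iloc[0]
                    raise ConfigurationError(
                        f"feature {d.name!r}: no cutoff for sex {bad!r}"
                    )
            else:
                cut = float(d.cutoff)
            if d.comparator == "gt":
                present = col > cut
            elif d.comparator == "lt":
                present = col < cut
            else:
                present = col == cut
            present = present & col.notna()
        out[d.name] = present.to_numpy(dtype=bool)
    return out
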