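"""Cohort CSV schema, typed reading/writing, and provenance sidecars.

The single cohort format is a UTF-8 CSV against a published data
dictionary.  Booleans are serialized as 0/1 and missing values as empty
cells — absent is never zero.  Bounded item ranges are enforced on load and
violations are schema errors naming the offending cell.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import (
    AKINESIA_ITEMS,
    LATERAL_TREMOR_ITEMS,
    MOCA_DOMAINS,
    PIGD_ITEMS,
    RIGIDITY_ITEMS,
    TREMOR_SCORE_ITEMS,
)

__all__ = [
    "ColumnSpec",
    "Schema",
    "clinical_schema",
    "schema_for_config",
    "read_cohort",
    "write_cohort",
    "file_sha256",
]


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # "id", "categorical", "int", "float", "bool"
    lo: float | None = None
    hi: float | None = None
    categories: tuple | None = None
    required: bool = False


class Schema:
    """Ordered collection of column specifications (the data dictionary)."""

    def __init__(self, columns):
        self.columns = {c.name: c for c in columns}

    def extend(self, columns) -> "Schema":
        merged = list(self.columns.values()) + [
            c for c in columns if c.name not in self.columns
        ]
        return Schema(merged)

    def __contains__(self, name):
        return name in self.columns

    def __getitem__(self, name):
        return self.columns[name]


def _item_cols(names, lo=0, hi=4):
    return [ColumnSpec(n, "int", lo, hi) for n in names]


def clinical_schema() -> Schema:
    """The shipped data dictionary for baseline clinical cohorts."""
    updrs3_items = sorted(
        set(
            RIGIDITY_ITEMS["left"] + RIGIDITY_ITEMS["right"]
            + AKINESIA_ITEMS["left"] + AKINESIA_ITEMS["right"]
            + LATERAL_TREMOR_ITEMS["left"] + LATERAL_TREMOR_ITEMS["right"]
            + PIGD_ITEMS + TREMOR_SCORE_ITEMS
        )
    )
    moca_item_max = {
        "moca_trail": 1, "moca_cube": 1, "moca_clock_contour": 1,
        "moca_clock_numbers": 1, "moca_clock_hands": 1,
        "moca_naming_lion": 1, "moca_naming_rhino": 1, "moca_naming_camel": 1,
        "moca_digits_forward": 1, "moca_digits_backward": 1,
        "moca_vigilance": 1, "moca_serial7": 3, "moca_repetition": 2,
        "moca_fluency": 1, "moca_abstraction": 2, "moca_recall": 5,
        "moca_orientation": 6,
    }
    assert set(moca_item_max) == {
        c for cols in MOCA_DOMAINS.values() for c in cols
    }
    history_flags = [
        "stroke", "head_injury", "depression", "anxiety", "diabetes",
        "smoking", "epilepsy", "encephalitis", "family_history",
    ]
    columns = (
        [
            ColumnSpec("subject_id", "id", required=True),
            ColumnSpec("sex", "categorical", categories=("male", "female")),
            ColumnSpec("education_years", "float", 0, 30),
            ColumnSpec("age_of_onset", "float", 0, 110),
            ColumnSpec("disease_duration", "float", 0, 60),
        ]
        + [ColumnSpec(f, "bool") for f in history_flags]
        + _item_cols(updrs3_items)
        + _item_cols(["updrs1_12", "updrs2_1", "updrs2_3", "updrs2_10"])
        + _item_cols(["scopa_7", "scopa_12", "scopa_13", "scopa_16"], 0, 3)
        + [ColumnSpec("scopa_total", "int", 0, 69)]
        + _item_cols(["stai_x1_6", "stai_x2_8", "stai_x2_11", "stai_x2_18"],
                     1, 4)
        + [
            ColumnSpec("stai_x1_total", "int", 20, 80),
            ColumnSpec("stai_x2_total", "int", 20, 80),
            ColumnSpec("rbdsq_6_1", "bool"),
            ColumnSpec("rbdsq_total", "int", 0, 13),
            ColumnSpec("upsit_total", "int", 0, 40),
            ColumnSpec("moca_zscore", "float", -10, 10),
        ]
        + [ColumnSpec(n, "int", 0, hi) for n, hi in moca_item_max.items()]
        + [
            ColumnSpec("moca", "int", 0, 30),
            ColumnSpec("moca_y2", "int", 0, 30),
            ColumnSpec("moca_y4", "int", 0, 30),
            ColumnSpec("decline", "bool"),
            ColumnSpec("trajectory", "categorical",
                       categories=("stable", "early_decline", "late_decline",
                                   "fluctuation")),
        ]
    )
    return Schema(columns)


def schema_for_config(config) -> Schema:
    """Clinical schema extended with a config's generated feature columns
    and the simulation ground-truth columns."""
    extra = [ColumnSpec(f.name, "bool") for f in config.feature_specs]
    extra += [
        ColumnSpec("sim_decline", "bool"),
        ColumnSpec("sim_pattern", "categorical",
                   categories=("stable", "early_decline", "late_decline",
                               "fluctuation")),
    ]
    return clinical_schema().extend(extra)


def _check_bounds(df, spec, errors):
    col = pd.to_numeric(df[spec.name], errors="coerce")
    raw_present = df[spec.name].notna()
    unparsable = raw_present & col.isna()
    for idx in df.index[unparsable]:
        errors.append(
            f"row {idx} (subject "
            f"{df.at[idx, 'subject_id'] if 'subject_id' in df else '?'}), "
            f"column {spec.name!r}: non-numeric value "
            f"{df.at[idx, spec.name]!r}"
        )
    lo = -np.inf if spec.lo is None else spec.lo
    hi = np.inf if spec.hi is None else spec.hi
    if spec.kind == "bool":
        lo, hi = 0, 1
    bad = col.notna() & ((col < lo) | (col > hi))
    for idx in df.index[bad]:
        errors.append(
            f"row {idx} (subject "
            f"{df.at[idx, 'subject_id'] if 'subject_id' in df else '?'}), "
            f"column {spec.name!r}: value {col[idx]:g} outside [{lo:g}, {hi:g}]"
        )
    return col


def read_cohort(path, schema: Schema | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV against the data dictionary.

    Unknown columns are kept but reported in ``df.attrs['unknown_columns']``
    (a warning is emitted); out-of-range values raise :class:`SchemaError`
    naming every offending cell; duplicate subject identifiers are an error.
    """
    schema = schema or clinical_schema()
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise SchemaError("cohort file lacks the required 'subject_id' column")
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if not dupes.empty:
        raise SchemaError(
            f"duplicate subject_id values: {sorted(dupes.unique())}"
        )
    unknown = [c for c in df.columns if c not in schema]
    if unknown:
        import warnings

        warnings.warn(
            f"ignoring unknown columns {unknown}", UserWarning, stacklevel=2
        )
    errors: list = []
    for name, spec in schema.columns.items():
        if name not in df.columns:
            if spec.required:
                errors.append(f"required column {name!r} missing")
            continue
        if spec.kind in ("int", "float", "bool"):
            values = _check_bounds(df, spec, errors)
            df[name] = values
        elif spec.kind == "categorical" and spec.categories:
            bad = df[name].notna() & ~df[name].isin(spec.categories)
            for idx in df.index[bad]:
                errors.append(
                    f"row {idx} (subject {df.at[idx, 'subject_id']}), column "
                    f"{name!r}: {df.at[idx, name]!r} not in {spec.categories}"
                )
    if errors:
        raise SchemaError("; ".join(errors))
    df.attrs["unknown_columns"] = unknown
    return df


def write_cohort(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a cohort CSV (booleans as 0/1, missing as empty cells) and, when
    provenance is available, a ``<path>.provenance.json`` sidecar."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
    provenance = provenance or df.attrs.get("provenance")
    if provenance is not None:
        sidecar = dict(provenance)
        sidecar["cohort_sha256"] = file_sha256(path)
        with open(f"{path}.provenance.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)


def file_sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
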