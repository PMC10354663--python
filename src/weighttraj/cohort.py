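"""Cohort schema, validation, and CSV I/O.

A cohort is one row per patient with demographics, clinical scores
(PANSS, GAF), vocational status, and body weight at three fixed time
points (baseline, 1 year, 2 years).  Weights and most clinical fields
may be missing; the two completeness filters below reproduce the two
nested analysis sets (complete weight data, then complete clinical
data) used throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "CATEGORICAL_LEVELS",
    "NUMERIC_COLUMNS",
    "CLINICAL_FIELDS",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "filter_complete_weight",
    "filter_complete_clinical",
]

#: Canonical column order of the cohort CSV.
COLUMNS = [
    "id",
    "age_baseline",
    "sex",
    "education",
    "vocational_baseline",
    "vocational_2yr",
    "dup_months",
    "admissions",
    "panss_total_bl",
    "panss_positive_bl",
    "panss_negative_bl",
    "panss_general_bl",
    "panss_total_2yr",
    "panss_positive_2yr",
    "panss_negative_2yr",
    "panss_general_2yr",
    "gaf_bl",
    "gaf_2yr",
    "height_m",
    "weight_bl",
    "weight_1yr",
    "weight_2yr",
]

#: Closed vocabularies for the categorical columns (lowercase on disk).
CATEGORICAL_LEVELS = {
    "sex": ("male", "female"),
    "education": ("tertiary_and_above", "below_tertiary"),
    "vocational_baseline": ("occupied", "unemployed"),
    "vocational_2yr": ("occupied", "unemployed"),
    "admissions": ("none", "one", "multiple"),
}

NUMERIC_COLUMNS = [c for c in COLUMNS if c not in CATEGORICAL_LEVELS and c != "id"]

WEIGHT_COLUMNS = ["weight_bl", "weight_1yr", "weight_2yr"]

#: Fields that must be present for a record to count as having
#: "complete clinical data" (the second, nested filter).  The PANSS
#: subscales are not required: the main battery uses totals only.
CLINICAL_FIELDS = [
    "education",
    "vocational_baseline",
    "vocational_2yr",
    "dup_months",
    "admissions",
    "panss_total_bl",
    "panss_total_2yr",
    "gaf_bl",
    "gaf_2yr",
]

#: Strings parsed as missing (case-insensitive), besides the empty cell.
MISSING_MARKERS = {"", "na"}


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the documented schema."""


@dataclass
class PatientRecord:
    """One cohort row.  ``None`` marks a missing value."""

    id: str
    age_baseline: float
    sex: str
    education: str | None
    vocational_baseline: str | None
    vocational_2yr: str | None
    dup_months: float | None
    admissions: str | None
    panss_total_bl: float | None
    panss_positive_bl: float | None
    panss_negative_bl: float | None
    panss_general_bl: float | None
    panss_total_2yr: float | None
    panss_positive_2yr: float | None
    panss_negative_2yr: float | None
    panss_general_2yr: float | None
    gaf_bl: float | None
    gaf_2yr: float | None
    height_m: float
    weight_bl: float | None
    weight_1yr: float | None
    weight_2yr: float | None

    @classmethod
    def from_row(cls, row: pd.Series) -> "PatientRecord":
        vals = {}
        for c in COLUMNS:
            v = row[c]
            if pd.isna(v):
                v = None
            vals[c] = v
        return cls(**vals)


@dataclass
class Cohort:
    """An ordered patient table plus a provenance note.

    The backing store is a pandas DataFrame with the columns in
    :data:`COLUMNS`; categorical columns hold the lowercase level
    strings, missing values are NaN/None.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterable[PatientRecord]:
        for _, row in self.df.iterrows():
            yield PatientRecord.from_row(row)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.provenance)


def _validate(df: pd.DataFrame, panss_tolerance: float | None = None) -> pd.DataFrame:
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing columns: {missing_cols}")
    df = df[COLUMNS].copy()

    dup = df["id"][df["id"].duplicated()].unique().tolist()
    if dup:
        raise CohortValidationError(f"duplicate patient ids: {dup}")

    for col, levels in CATEGORICAL_LEVELS.items():
        bad = df[col].dropna()[~df[col].dropna().isin(levels)]
        if len(bad):
            raise CohortValidationError(
                f"unknown level in column '{col}': {bad.iloc[0]!r} "
                f"(allowed: {list(levels)})"
            )

    # height unit heuristic: values > 3 are centimetres
    h = df["height_m"].astype(float)
    df["height_m"] = np.where(h > 3, h / 100.0, h)
    bad_h = df.index[(df["height_m"] <= 0.5) | (df["height_m"] >= 2.5)]
    if len(bad_h):
        raise CohortValidationError(
            f"height out of range (0.5, 2.5) m after unit normalization "
            f"at row(s) {bad_h.tolist()}"
        )

    for col in WEIGHT_COLUMNS:
        w = df[col].astype(float)
        bad = df.index[w.notna() & (w <= 0)]
        if len(bad):
            raise CohortValidationError(
                f"non-positive weight in '{col}' at row(s) {bad.tolist()}"
            )

    if panss_tolerance is not None:
        for when in ("bl", "2yr"):
            cols = [f"panss_{p}_{when}" for p in ("positive", "negative", "general")]
            total = df[f"panss_total_{when}"].astype(float)
            comp = df[cols].astype(float).sum(axis=1, min_count=3)
            off = (total - comp).abs() > panss_tolerance
            off &= total.notna() & comp.notna()
            if off.any():
                warnings.warn(
                    f"PANSS total != positive+negative+general at {when} "
                    f"for {int(off.sum())} record(s)",
                    stacklevel=3,
                )
    return df


def make_cohort(df: pd.DataFrame, provenance: str = "",
                panss_tolerance: float | None = None) -> Cohort:
    """Validate a raw DataFrame and wrap it as a :class:`Cohort`."""
    return Cohort(_validate(df, panss_tolerance), provenance)


def read_cohort(path: str | Path, panss_tolerance: float | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    Missing cells may be empty or "NA" (case-insensitive).  Heights
    above 3 are interpreted as centimetres and divided by 100.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortValidationError(f"{path}: missing columns: {missing_cols}")
    raw = raw[COLUMNS]
    df = raw.map(lambda v: np.nan if str(v).strip().lower() in MISSING_MARKERS else v)
    for col in NUMERIC_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[df[col].notna() & bad.isna()].tolist()
            raise CohortValidationError(
                f"{path}: non-numeric value in '{col}' at row(s) {rows}"
            ) from None
    if df["id"].isna().any():
        raise CohortValidationError(f"{path}: missing patient id")
    return make_cohort(df, provenance=str(path), panss_tolerance=panss_tolerance)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as CSV; missing values become empty cells.

    ``read_cohort(write_cohort(x))`` reproduces ``x`` field for field.
    """
    cohort.df.to_csv(path, index=False, na_rep="")


def filter_complete_weight(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition into (all three weights present, the rest)."""
    mask = cohort.df[WEIGHT_COLUMNS].notna().all(axis=1)
    complete = Cohort(cohort.df[mask].reset_index(drop=True),
                      cohort.provenance + " [complete weight]")
    incomplete = Cohort(cohort.df[~mask].reset_index(drop=True),
                        cohort.provenance + " [incomplete weight]")
    return complete, incomplete


def filter_complete_clinical(cohort: Cohort,
                             fields: list[str] | None = None) -> Cohort:
    """Keep records with every required clinical field present."""
    fields = CLINICAL_FIELDS if fields is None else fields
    mask = cohort.df[fields].notna().all(axis=1)
    return Cohort(cohort.df[mask].reset_index(drop=True),
                  cohort.provenance + " [complete clinical]")
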