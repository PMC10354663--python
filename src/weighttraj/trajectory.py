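"""Interval weight-change categorization and 2-year risk-profile assignment.

The method: for each patient compute the percentage weight change over
each yearly interval, map each change onto one of four categories
(clinically significant gain is >=7% of the interval's starting
weight), and assign one of five named 2-year risk profiles from the
ordered pair of yearly categories via an explicit 4x4 grouping matrix.

The matrix is stored cell-by-cell rather than derived from rules: the
narrative examples ("increase severe then decrease", "maintain then
increase severe", ...) under-determine several cells that only the
published grouping table fixes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from math import isfinite

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "ChangeCategory",
    "TrajectoryProfile",
    "PatientTrajectory",
    "ChangeCrossTab",
    "GROUPING_MATRIX",
    "REFERENCE_CROSSTAB_COUNTS",
    "percent_change",
    "categorize_change",
    "categorize_changes",
    "assign_profile",
    "classify_patient",
    "classify_cohort",
    "cross_tabulate",
    "profile_totals",
    "round_half_up",
]


class ChangeCategory(str, Enum):
    """Four-level categorization of one interval's % weight change.

    The bands partition the real line: gain >=7% is severe, gain in
    (1, 7)% mild, change within [-1, 1]% maintain, loss >1% decrease.
    """

    INCREASE_SEVERE = "increase_severe"
    INCREASE_MILD = "increase_mild"
    MAINTAIN = "maintain"
    DECREASE = "decrease"


class TrajectoryProfile(str, Enum):
    """Five named 2-year weight-gain risk profiles."""

    SUPER_HIGH_RISK = "super_high_risk"
    HIGH_RISK_MITIGATED = "high_risk_mitigated"
    AT_RISK = "at_risk"
    DELAYED_RISK = "delayed_risk"
    LOW_RISK = "low_risk"


#: Display/index order of categories (rows = year-1, columns = year-2).
CATEGORY_ORDER = [
    ChangeCategory.INCREASE_SEVERE,
    ChangeCategory.INCREASE_MILD,
    ChangeCategory.MAINTAIN,
    ChangeCategory.DECREASE,
]

PROFILE_ORDER = [
    TrajectoryProfile.SUPER_HIGH_RISK,
    TrajectoryProfile.HIGH_RISK_MITIGATED,
    TrajectoryProfile.AT_RISK,
    TrajectoryProfile.DELAYED_RISK,
    TrajectoryProfile.LOW_RISK,
]

_C = ChangeCategory
_P = TrajectoryProfile

#: The full 16-cell grouping matrix, (year-1 category, year-2 category)
#: -> profile.
GROUPING_MATRIX: dict[tuple[ChangeCategory, ChangeCategory], TrajectoryProfile] = {
    (_C.INCREASE_SEVERE, _C.INCREASE_SEVERE): _P.SUPER_HIGH_RISK,
    (_C.INCREASE_SEVERE, _C.INCREASE_MILD): _P.SUPER_HIGH_RISK,
    (_C.INCREASE_SEVERE, _C.MAINTAIN): _P.HIGH_RISK_MITIGATED,
    (_C.INCREASE_SEVERE, _C.DECREASE): _P.HIGH_RISK_MITIGATED,
    (_C.INCREASE_MILD, _C.INCREASE_SEVERE): _P.SUPER_HIGH_RISK,
    (_C.INCREASE_MILD, _C.INCREASE_MILD): _P.AT_RISK,
    (_C.INCREASE_MILD, _C.MAINTAIN): _P.LOW_RISK,
    (_C.INCREASE_MILD, _C.DECREASE): _P.LOW_RISK,
    (_C.MAINTAIN, _C.INCREASE_SEVERE): _P.DELAYED_RISK,
    (_C.MAINTAIN, _C.INCREASE_MILD): _P.DELAYED_RISK,
    (_C.MAINTAIN, _C.MAINTAIN): _P.LOW_RISK,
    (_C.MAINTAIN, _C.DECREASE): _P.LOW_RISK,
    (_C.DECREASE, _C.INCREASE_SEVERE): _P.DELAYED_RISK,
    (_C.DECREASE, _C.INCREASE_MILD): _P.DELAYED_RISK,
    (_C.DECREASE, _C.MAINTAIN): _P.LOW_RISK,
    (_C.DECREASE, _C.DECREASE): _P.LOW_RISK,
}

#: Published 4x4 cross-tabulation of yearly change categories from the
#: EPIP 2-year first-episode psychosis cohort (n=391); rows year-1
#: category, columns year-2 category, both in CATEGORY_ORDER.  Used by
#: the built-in replay fixture.
REFERENCE_CROSSTAB_COUNTS = np.array(
    [
        [57, 79, 34, 99],
        [15, 17, 9, 29],
        [5, 3, 3, 3],
        [16, 10, 3, 9],
    ]
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as clinical tables are printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_change(w_start: float, w_end: float) -> float:
    """Percentage change from ``w_start`` to ``w_end`` (kg, both > 0)."""
    if not (w_start > 0 and w_end > 0):
        raise ValueError(f"weights must be positive, got {w_start}, {w_end}")
    return 100.0 * (w_end - w_start) / w_start


def categorize_change(pct: float) -> ChangeCategory:
    """Map a finite percentage weight change onto its category."""
    if not isfinite(pct):
        raise ValueError(f"percentage change must be finite, got {pct}")
    if pct >= 7.0:
        return ChangeCategory.INCREASE_SEVERE
    if pct > 1.0:
        return ChangeCategory.INCREASE_MILD
    if pct >= -1.0:
        return ChangeCategory.MAINTAIN
    return ChangeCategory.DECREASE


def categorize_changes(pct: np.ndarray) -> np.ndarray:
    """Vectorized :func:`categorize_change`; returns category values."""
    pct = np.asarray(pct, dtype=float)
    if not np.isfinite(pct).all():
        raise ValueError("percentage changes must be finite")
    return np.select(
        [pct >= 7.0, pct > 1.0, pct >= -1.0],
        [_C.INCREASE_SEVERE.value, _C.INCREASE_MILD.value, _C.MAINTAIN.value],
        default=_C.DECREASE.value,
    )


def assign_profile(cat1: ChangeCategory, cat2: ChangeCategory) -> TrajectoryProfile:
    """Look up the 2-year risk profile for a (year-1, year-2) pair."""
    return GROUPING_MATRIX[(ChangeCategory(cat1), ChangeCategory(cat2))]


@dataclass
class PatientTrajectory:
    """Per-patient classification result."""

    id: str
    pct_change_yr1: float
    pct_change_yr2: float
    cat_yr1: ChangeCategory
    cat_yr2: ChangeCategory
    profile: TrajectoryProfile
    total_pct_change_from_baseline: float


def classify_patient(rec, yr2_base: str = "interval") -> PatientTrajectory:
    """Classify one patient from their three weights.

    ``yr2_base`` selects the denominator of the second interval's
    percentage: "interval" (the 1-year weight; default) or "baseline".
    All three weights must be present.
    """
    for name in ("weight_bl", "weight_1yr", "weight_2yr"):
        if getattr(rec, name) is None or pd.isna(getattr(rec, name)):
            raise ValueError(f"cannot classify patient {rec.id}: missing {name}")
    p1 = percent_change(rec.weight_bl, rec.weight_1yr)
    base2 = rec.weight_1yr if yr2_base == "interval" else rec.weight_bl
    if yr2_base not in ("interval", "baseline"):
        raise ValueError(f"yr2_base must be 'interval' or 'baseline', got {yr2_base!r}")
    p2 = percent_change(base2, rec.weight_2yr)
    c1, c2 = categorize_change(p1), categorize_change(p2)
    return PatientTrajectory(
        id=rec.id,
        pct_change_yr1=p1,
        pct_change_yr2=p2,
        cat_yr1=c1,
        cat_yr2=c2,
        profile=assign_profile(c1, c2),
        total_pct_change_from_baseline=percent_change(rec.weight_bl, rec.weight_2yr),
    )


def classify_cohort(cohort: Cohort, yr2_base: str = "interval") -> pd.DataFrame:
    """Vectorized classification of every record with complete weights.

    Returns one row per patient: id, pct_yr1, pct_yr2, cat_yr1,
    cat_yr2, profile, total_pct.  Records with a missing weight raise;
    filter with :func:`weighttraj.cohort.filter_complete_weight` first.
    """
    if yr2_base not in ("interval", "baseline"):
        raise ValueError(f"yr2_base must be 'interval' or 'baseline', got {yr2_base!r}")
    df = cohort.df
    w = df[["weight_bl", "weight_1yr", "weight_2yr"]].astype(float)
    if w.isna().any().any():
        bad = df.loc[w.isna().any(axis=1), "id"].tolist()
        raise ValueError(f"missing weights for patient(s) {bad[:5]}")
    w0, w1, w2 = (w[c].to_numpy() for c in w.columns)
    p1 = 100.0 * (w1 - w0) / w0
    base2 = w1 if yr2_base == "interval" else w0
    p2 = 100.0 * (w2 - base2) / base2
    c1 = categorize_changes(p1)
    c2 = categorize_changes(p2)
    prof = np.array(
        [assign_profile(a, b).value for a, b in zip(c1, c2)], dtype=object
    )
    return pd.DataFrame(
        {
            "id": df["id"].to_numpy(),
            "pct_yr1": p1,
            "pct_yr2": p2,
            "cat_yr1": c1,
            "cat_yr2": c2,
            "profile": prof,
            "total_pct": 100.0 * (w2 - w0) / w0,
        }
    )


@dataclass
class ChangeCrossTab:
    """4x4 counts of (year-1 category x year-2 category) with marginals."""

    counts: pd.DataFrame  # index/columns: category values in CATEGORY_ORDER

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("cross-tab counts must be non-negative")

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def profile_of_cell(self, row: str, col: str) -> TrajectoryProfile:
        return assign_profile(ChangeCategory(row), ChangeCategory(col))

    def to_report_frame(self) -> pd.DataFrame:
        """Long-format report: one row per cell with its profile label."""
        rows = []
        n = self.grand_total
        for r in self.counts.index:
            for c in self.counts.columns:
                cnt = int(self.counts.loc[r, c])
                rows.append(
                    {
                        "cat_yr1": r,
                        "cat_yr2": c,
                        "profile": self.profile_of_cell(r, c).value,
                        "count": cnt,
                        "pct": round_half_up(100.0 * cnt / n, 1) if n else None,
                    }
                )
        return pd.DataFrame(rows)


def cross_tabulate(trajectories: pd.DataFrame | list) -> ChangeCrossTab:
    """Cross-tabulate year-1 vs year-2 categories (empty input allowed)."""
    if isinstance(trajectories, pd.DataFrame):
        c1 = trajectories["cat_yr1"] if len(trajectories) else pd.Series(dtype=object)
        c2 = trajectories["cat_yr2"] if len(trajectories) else pd.Series(dtype=object)
    else:
        c1 = pd.Series([t.cat_yr1.value for t in trajectories], dtype=object)
        c2 = pd.Series([t.cat_yr2.value for t in trajectories], dtype=object)
    order = [c.value for c in CATEGORY_ORDER]
    tab = pd.crosstab(c1, c2).reindex(index=order, columns=order, fill_value=0)
    tab = tab.fillna(0).astype(int)
    tab.index.name, tab.columns.name = "cat_yr1", "cat_yr2"
    return ChangeCrossTab(tab)


def profile_totals(tab: ChangeCrossTab) -> pd.DataFrame:
    """Per-profile membership counts and percentages (1 d.p., half-up).

    With a grand total of zero the counts are zero and the percentage
    column is left missing.
    """
    counts = {p.value: 0 for p in PROFILE_ORDER}
    for r in tab.counts.index:
        for c in tab.counts.columns:
            counts[tab.profile_of_cell(r, c).value] += int(tab.counts.loc[r, c])
    n = tab.grand_total
    out = pd.DataFrame(
        {
            "profile": [p.value for p in PROFILE_ORDER],
            "count": [counts[p.value] for p in PROFILE_ORDER],
        }
    )
    if n:
        out["pct"] = [round_half_up(100.0 * c / n, 1) for c in out["count"]]
    else:
        out["pct"] = np.nan
    return out


def reference_crosstab() -> ChangeCrossTab:
    """The published 16-cell cross-tabulation as a ChangeCrossTab."""
    order = [c.value for c in CATEGORY_ORDER]
    tab = pd.DataFrame(REFERENCE_CROSSTAB_COUNTS, index=order, columns=order)
    tab.index.name, tab.columns.name = "cat_yr1", "cat_yr2"
    return ChangeCrossTab(tab)
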