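"""Between-group comparison battery.

Three test families, matching how such cohorts are conventionally
compared: pooled-variance Student's t for a two-group continuous
comparison (df = n1+n2-2 on pairwise-complete cases), Pearson
chi-square without continuity correction for categoricals, and one-way
ANOVA for continuous variables across more than two groups.  Missing
values are handled pairwise per variable, never listwise across the
battery, and no multiple-testing correction is applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, filter_complete_weight
from .trajectory import CATEGORY_ORDER, ChangeCategory

__all__ = [
    "ComparisonResult",
    "pooled_t",
    "pearson_chi2",
    "one_way_anova",
    "compare_missingness",
    "compare_yr1_groups",
    "compare_continued_gainers",
    "results_to_frame",
    "CONTINUOUS_BATTERY",
    "CATEGORICAL_BATTERY",
]

log = logging.getLogger(__name__)

#: Default variable lists for the two-group and year-1 batteries.
CONTINUOUS_BATTERY = ["age_baseline", "dup_months", "panss_total_bl", "gaf_bl"]
CATEGORICAL_BATTERY = ["sex", "education", "vocational_baseline", "admissions"]


@dataclass
class ComparisonResult:
    """One statistical comparison of a variable between groups."""

    variable: str
    test: str  # students_t | one_way_anova | chi_square
    statistic: float | None = None
    df: float | tuple[float, float] | None = None
    p: float | None = None
    groups: dict = field(default_factory=dict)
    computable: bool = True
    note: str = ""


def _summary(x: np.ndarray) -> dict:
    return {
        "n": int(len(x)),
        "mean": float(np.mean(x)) if len(x) else None,
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else None,
    }


def pooled_t(variable: str, a, b, names=("group1", "group2")) -> ComparisonResult:
    """Two-sided pooled-variance Student's t on pairwise-complete cases."""
    a = np.asarray(pd.Series(a).dropna(), dtype=float)
    b = np.asarray(pd.Series(b).dropna(), dtype=float)
    groups = {names[0]: _summary(a), names[1]: _summary(b)}
    if len(a) < 2 or len(b) < 2:
        return ComparisonResult(variable, "students_t", groups=groups,
                                computable=False, note="a group has < 2 cases")
    res = sps.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    stat = float(res.statistic)
    if not np.isfinite(stat):  # zero pooled variance, identical constants
        return ComparisonResult(variable, "students_t", groups=groups,
                                computable=False, note="zero pooled variance")
    return ComparisonResult(variable, "students_t", stat, df,
                            float(res.pvalue), groups)


def pearson_chi2(variable: str, table: pd.DataFrame | np.ndarray) -> ComparisonResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    tab = pd.DataFrame(table)
    tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
    groups = {str(i): tab.loc[i].to_dict() for i in tab.index}
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return ComparisonResult(variable, "chi_square", groups=groups,
                                computable=False,
                                note="contingency table smaller than 2x2")
    chi2, p, df, expected = sps.chi2_contingency(tab.to_numpy(), correction=False)
    if (expected < 5).any():
        log.warning("%s: %d expected cell count(s) below 5",
                    variable, int((expected < 5).sum()))
    return ComparisonResult(variable, "chi_square", float(chi2), int(df),
                            float(p), groups)


def one_way_anova(variable: str, samples: dict[str, np.ndarray]) -> ComparisonResult:
    """One-way ANOVA across named groups (pairwise-complete per group)."""
    clean = {k: np.asarray(pd.Series(v).dropna(), dtype=float)
             for k, v in samples.items()}
    groups = {k: _summary(v) for k, v in clean.items()}
    usable = {k: v for k, v in clean.items() if len(v) >= 2}
    if len(usable) < 2:
        return ComparisonResult(variable, "one_way_anova", groups=groups,
                                computable=False,
                                note="fewer than 2 groups with >= 2 cases")
    if len(usable) < len(clean):
        return ComparisonResult(variable, "one_way_anova", groups=groups,
                                computable=False,
                                note="a group has < 2 cases")
    arrays = list(usable.values())
    res = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    stat = float(res.statistic)
    if not np.isfinite(stat):
        return ComparisonResult(variable, "one_way_anova", groups=groups,
                                computable=False, note="zero within-group variance")
    return ComparisonResult(variable, "one_way_anova", stat, (k - 1, n - k),
                            float(res.pvalue), groups)


def _two_group_battery(df: pd.DataFrame, group_col: str, names,
                       continuous, categorical) -> list[ComparisonResult]:
    out = []
    g1 = df[df[group_col] == names[0]]
    g2 = df[df[group_col] == names[1]]
    for var in categorical:
        tab = pd.crosstab(df[group_col], df[var])
        tab = tab.reindex(index=list(names)).fillna(0).astype(int)
        out.append(pearson_chi2(var, tab))
    for var in continuous:
        out.append(pooled_t(var, g1[var], g2[var], names=names))
    return out


def compare_missingness(cohort: Cohort,
                        continuous: list[str] | None = None,
                        categorical: list[str] | None = None,
                        ) -> list[ComparisonResult]:
    """Compare baseline characteristics of patients with vs without
    complete 2-year weight data (chi-square for categoricals, pooled t
    for continuous variables, pairwise-complete per variable)."""
    continuous = CONTINUOUS_BATTERY if continuous is None else continuous
    categorical = CATEGORICAL_BATTERY if categorical is None else categorical
    complete, incomplete = filter_complete_weight(cohort)
    df = cohort.df.copy()
    has_all = df[["weight_bl", "weight_1yr", "weight_2yr"]].notna().all(axis=1)
    df["_weight_data"] = np.where(has_all, "complete", "incomplete")
    return _two_group_battery(df, "_weight_data", ("complete", "incomplete"),
                              continuous, categorical)


def compare_yr1_groups(cohort: Cohort, trajectories: pd.DataFrame,
                       continuous: list[str] | None = None,
                       categorical: list[str] | None = None,
                       ) -> list[ComparisonResult]:
    """Compare variables across the four first-year change categories
    (one-way ANOVA for continuous, Pearson chi-square for categorical;
    admissions x category is the 3x4 table, df = 6)."""
    continuous = CONTINUOUS_BATTERY if continuous is None else continuous
    categorical = CATEGORICAL_BATTERY if categorical is None else categorical
    df = cohort.df.merge(trajectories[["id", "cat_yr1"]], on="id", how="inner")
    order = [c.value for c in CATEGORY_ORDER]
    out = []
    for var in categorical:
        tab = pd.crosstab(df[var], df["cat_yr1"])
        tab = tab.reindex(columns=order).fillna(0).astype(int)
        out.append(pearson_chi2(var, tab))
    for var in continuous:
        samples = {c: df.loc[df["cat_yr1"] == c, var] for c in order}
        out.append(one_way_anova(var, samples))
    return out


def compare_continued_gainers(cohort: Cohort, trajectories: pd.DataFrame,
                              split: str = "any_gain",
                              continuous: list[str] | None = None,
                              categorical: list[str] | None = None,
                              ) -> list[ComparisonResult]:
    """Among patients with severe first-year gain, compare those who
    continued to gain in year 2 with those who did not.

    ``split`` defines "continued to gain": "any_gain" (year-2 category
    severe or mild; default) or "severe_only".
    """
    if split not in ("any_gain", "severe_only"):
        raise ValueError(f"split must be 'any_gain' or 'severe_only', got {split!r}")
    continuous = CONTINUOUS_BATTERY if continuous is None else continuous
    categorical = CATEGORICAL_BATTERY if categorical is None else categorical
    traj = trajectories[trajectories["cat_yr1"]
                        == ChangeCategory.INCREASE_SEVERE.value]
    df = cohort.df.merge(traj[["id", "cat_yr2"]], on="id", how="inner")
    gaining = ([ChangeCategory.INCREASE_SEVERE.value,
                ChangeCategory.INCREASE_MILD.value]
               if split == "any_gain"
               else [ChangeCategory.INCREASE_SEVERE.value])
    df["_continued"] = np.where(df["cat_yr2"].isin(gaining),
                                "continued", "not_continued")
    return _two_group_battery(df, "_continued", ("continued", "not_continued"),
                              continuous, categorical)


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy one-row-per-comparison frame for CSV/JSON export."""
    rows = []
    for r in results:
        df_str = (f"{r.df[0]},{r.df[1]}" if isinstance(r.df, tuple)
                  else ("" if r.df is None else str(r.df)))
        rows.append(
            {
                "variable": r.variable,
                "test": r.test,
                "statistic": r.statistic,
                "df": df_str,
                "p": r.p,
                "computable": r.computable,
                "note": r.note,
                "groups": repr(r.groups),
            }
        )
    return pd.DataFrame(rows)
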