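"""Comparison battery against hand-derived closed forms and on
simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from weighttraj.cohort import make_cohort
from weighttraj.simulate import GeneratorConfig, MissingnessModel, generate_cohort
from weighttraj.stats import (
    compare_continued_gainers,
    compare_missingness,
    compare_yr1_groups,
    one_way_anova,
    pearson_chi2,
    pooled_t,
    results_to_frame,
)
from weighttraj.trajectory import classify_cohort
from conftest import make_rows


def hand_pooled_t(a, b):
    """Closed-form pooled-variance t, written independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def hand_chi2(tab):
    tab = np.asarray(tab, float)
    expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
    return ((tab - expected) ** 2 / expected).sum()


def hand_anova_f(groups):
    all_ = np.concatenate(groups)
    grand = all_.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    k, n = len(groups), len(all_)
    return (ssb / (k - 1)) / (ssw / (n - k))


def test_pooled_t_closed_form():
    r = pooled_t("x", [1, 2, 3], [2, 3, 4])
    assert r.statistic == pytest.approx(-1.224744871, abs=1e-9)
    assert r.statistic == pytest.approx(hand_pooled_t([1, 2, 3], [2, 3, 4]), abs=1e-9)
    assert r.df == 4
    assert r.groups["group1"]["n"] == 3


def test_pooled_t_identical_groups():
    r = pooled_t("x", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == pytest.approx(0.0)
    assert r.p == pytest.approx(1.0)


def test_pooled_t_degenerate():
    assert not pooled_t("x", [1.0], [1.0, 2.0]).computable
    assert not pooled_t("x", [2.0, 2.0], [2.0, 2.0]).computable  # zero variance


def test_chi2_closed_form():
    r = pearson_chi2("x", [[10, 20], [20, 10]])
    assert r.statistic == pytest.approx(6.666666667, abs=1e-9)
    assert r.statistic == pytest.approx(hand_chi2([[10, 20], [20, 10]]), abs=1e-9)
    assert r.df == 1


def test_chi2_degenerate_table():
    assert not pearson_chi2("x", [[5, 5]]).computable
    assert not pearson_chi2("x", [[5, 0], [3, 0]]).computable  # empty column


def test_anova_closed_form():
    samples = {"a": [1, 2], "b": [3, 4], "c": [5, 6]}
    r = one_way_anova("x", samples)
    f = hand_anova_f([[1, 2], [3, 4], [5, 6]])
    assert f == pytest.approx(16.0)  # MSB 8.0 over MSW 0.5
    assert r.statistic == pytest.approx(f, abs=1e-9)
    assert r.df == (2, 3)


def test_anova_small_group_flagged():
    r = one_way_anova("x", {"a": [1, 2], "b": [3.0], "c": [5, 6]})
    assert not r.computable


def _cohort_with_missing_pattern():
    # 6 patients: 3 complete weights, 3 with weight_2yr missing
    df = make_rows(
        6,
        weight_2yr=[72.0, 72.0, 72.0, np.nan, np.nan, np.nan],
        sex=["male", "male", "female", "female", "female", "male"],
        age_baseline=[20.0, 22.0, 24.0, 30.0, 32.0, 31.0],
        dup_months=[5.0, 6.0, np.nan, 20.0, 22.0, 21.0],
    )
    return make_cohort(df)


def test_compare_missingness_battery_and_pairwise_df():
    results = {r.variable: r for r in compare_missingness(_cohort_with_missing_pattern())}
    assert set(results) >= {"sex", "age_baseline", "dup_months"}
    age = results["age_baseline"]
    assert age.test == "students_t"
    assert age.df == 4  # 3+3-2, all ages present
    # dup_months has one missing case in the complete group: df drops to 3
    assert results["dup_months"].df == 3
    assert results["dup_months"].groups["complete"]["n"] == 2
    t = hand_pooled_t([20, 22, 24], [30, 32, 31])
    assert age.statistic == pytest.approx(t, abs=1e-9)


def test_compare_missingness_single_stratum_not_computable():
    cohort = make_cohort(make_rows(4))  # nobody missing
    results = {r.variable: r for r in compare_missingness(cohort)}
    assert all(not r.computable for r in results.values())


def test_compare_yr1_groups_admissions_df6():
    cfg = GeneratorConfig(n=800, missingness=MissingnessModel(enabled=False),
                          clinical_missing_rate=0.0)
    cohort = generate_cohort(cfg, seed=2)
    traj = classify_cohort(cohort)
    results = {r.variable: r for r in compare_yr1_groups(cohort, traj)}
    adm = results["admissions"]
    assert adm.test == "chi_square"
    assert adm.df == 6  # 3 admission levels x 4 year-1 categories
    assert results["age_baseline"].test == "one_way_anova"
    k_minus_1, n_minus_k = results["age_baseline"].df
    assert k_minus_1 == 3 and n_minus_k == 800 - 4


def test_continued_gainers_split_rules():
    cfg = GeneratorConfig(n=600, missingness=MissingnessModel(enabled=False),
                          clinical_missing_rate=0.0)
    cohort = generate_cohort(cfg, seed=4)
    traj = classify_cohort(cohort)
    severe1 = traj[traj["cat_yr1"] == "increase_severe"]
    any_gain = {r.variable: r for r in
                compare_continued_gainers(cohort, traj, split="any_gain")}
    n_cont = any_gain["age_baseline"].groups["continued"]["n"]
    n_not = any_gain["age_baseline"].groups["not_continued"]["n"]
    assert n_cont + n_not == len(severe1)
    assert n_cont == (severe1["cat_yr2"].isin(["increase_severe", "increase_mild"])).sum()
    sev_only = {r.variable: r for r in
                compare_continued_gainers(cohort, traj, split="severe_only")}
    assert (sev_only["age_baseline"].groups["continued"]["n"]
            == (severe1["cat_yr2"] == "increase_severe").sum())
    with pytest.raises(ValueError):
        compare_continued_gainers(cohort, traj, split="bogus")


def test_continued_gainers_empty_restriction_no_crash():
    df = make_rows(3, weight_1yr=60.0, weight_2yr=60.0)  # nobody severe in yr1
    cohort = make_cohort(df)
    traj = classify_cohort(cohort)
    results = compare_continued_gainers(cohort, traj)
    assert results and all(not r.computable for r in results)


def test_results_to_frame_tidy():
    frame = results_to_frame(compare_missingness(_cohort_with_missing_pattern()))
    assert {"variable", "test", "statistic", "df", "p"} <= set(frame.columns)
    assert len(frame) == 8
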