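"""Weight-change categorization, profile assignment, cross-tabulation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weighttraj.cohort import make_cohort
from weighttraj.trajectory import (
    CATEGORY_ORDER,
    GROUPING_MATRIX,
    PROFILE_ORDER,
    ChangeCategory,
    TrajectoryProfile,
    assign_profile,
    categorize_change,
    categorize_changes,
    classify_cohort,
    classify_patient,
    cross_tabulate,
    percent_change,
    profile_totals,
    reference_crosstab,
    round_half_up,
)
from conftest import make_rows

C = ChangeCategory
P = TrajectoryProfile


def oracle_category(pct: float) -> str:
    """Independent if-chain restatement of the published bands."""
    if pct >= 7:
        return "increase_severe"
    elif pct < 7 and pct > 1:
        return "increase_mild"
    elif pct <= 1 and pct >= -1:
        return "maintain"
    elif pct < -1:
        return "decrease"
    raise AssertionError(pct)


@pytest.mark.parametrize(
    "w0,w1,expected",
    [(60.0, 64.2, 7.0), (60.0, 60.0, 0.0), (80.0, 79.0, -1.25)],
)
def test_percent_change_arithmetic(w0, w1, expected):
    assert percent_change(w0, w1) == pytest.approx(expected)


def test_percent_change_rejects_nonpositive():
    with pytest.raises(ValueError):
        percent_change(0.0, 60.0)
    with pytest.raises(ValueError):
        percent_change(60.0, -1.0)


@pytest.mark.parametrize(
    "pct,expected",
    [
        (7.0, C.INCREASE_SEVERE),
        (40.0, C.INCREASE_SEVERE),
        (6.999999, C.INCREASE_MILD),
        (1.0000001, C.INCREASE_MILD),
        (1.0, C.MAINTAIN),
        (0.0, C.MAINTAIN),
        (-1.0, C.MAINTAIN),
        (-1.0000001, C.DECREASE),
        (-15.0, C.DECREASE),
    ],
)
def test_category_boundaries(pct, expected):
    assert categorize_change(pct) is expected
    assert categorize_changes(np.array([pct]))[0] == expected.value


def test_categorize_rejects_nonfinite():
    with pytest.raises(ValueError):
        categorize_change(float("nan"))
    with pytest.raises(ValueError):
        categorize_changes(np.array([1.0, np.inf]))


@settings(max_examples=300, derandomize=True)
@given(st.floats(min_value=-100, max_value=100, allow_nan=False))
def test_category_partition_property(pct):
    """Exactly one band holds for every finite percentage and the
    scalar, vectorized and oracle codings agree."""
    preds = [pct >= 7, 7 > pct > 1, 1 >= pct >= -1, pct < -1]
    assert sum(preds) == 1
    cat = categorize_change(pct)
    assert cat.value == oracle_category(pct)
    assert categorize_changes(np.array([pct]))[0] == cat.value


def test_grouping_matrix_total_on_16_pairs():
    seen = {}
    for c1, c2 in itertools.product(list(C), list(C)):
        seen[(c1, c2)] = assign_profile(c1, c2)
    assert len(seen) == 16
    assert set(seen.values()) == set(P)
    # the published matrix, row by row
    assert seen[(C.INCREASE_SEVERE, C.INCREASE_SEVERE)] is P.SUPER_HIGH_RISK
    assert seen[(C.INCREASE_SEVERE, C.INCREASE_MILD)] is P.SUPER_HIGH_RISK
    assert seen[(C.INCREASE_SEVERE, C.MAINTAIN)] is P.HIGH_RISK_MITIGATED
    assert seen[(C.INCREASE_SEVERE, C.DECREASE)] is P.HIGH_RISK_MITIGATED
    assert seen[(C.INCREASE_MILD, C.INCREASE_SEVERE)] is P.SUPER_HIGH_RISK
    assert seen[(C.INCREASE_MILD, C.INCREASE_MILD)] is P.AT_RISK
    assert seen[(C.INCREASE_MILD, C.MAINTAIN)] is P.LOW_RISK
    assert seen[(C.INCREASE_MILD, C.DECREASE)] is P.LOW_RISK
    assert seen[(C.MAINTAIN, C.INCREASE_SEVERE)] is P.DELAYED_RISK
    assert seen[(C.MAINTAIN, C.INCREASE_MILD)] is P.DELAYED_RISK
    assert seen[(C.MAINTAIN, C.MAINTAIN)] is P.LOW_RISK
    assert seen[(C.MAINTAIN, C.DECREASE)] is P.LOW_RISK
    assert seen[(C.DECREASE, C.INCREASE_SEVERE)] is P.DELAYED_RISK
    assert seen[(C.DECREASE, C.INCREASE_MILD)] is P.DELAYED_RISK
    assert seen[(C.DECREASE, C.MAINTAIN)] is P.LOW_RISK
    assert seen[(C.DECREASE, C.DECREASE)] is P.LOW_RISK


@pytest.mark.parametrize(
    "weights,cats,profile",
    [
        ((60.0, 66.0, 72.0), (C.INCREASE_SEVERE, C.INCREASE_SEVERE), P.SUPER_HIGH_RISK),
        ((60.0, 60.0, 60.0), (C.MAINTAIN, C.MAINTAIN), P.LOW_RISK),
        # -1.667% then +10.169% by hand arithmetic
        ((60.0, 59.0, 65.0), (C.DECREASE, C.INCREASE_SEVERE), P.DELAYED_RISK),
    ],
)
def test_classify_patient(weights, cats, profile):
    rows = make_rows(1, weight_bl=weights[0], weight_1yr=weights[1],
                     weight_2yr=weights[2])
    rec = next(make_cohort(rows).records())
    t = classify_patient(rec)
    assert (t.cat_yr1, t.cat_yr2) == cats
    assert t.profile is profile
    assert t.total_pct_change_from_baseline == pytest.approx(
        100 * (weights[2] - weights[0]) / weights[0]
    )


def test_classify_patient_hand_percentages():
    rows = make_rows(1, weight_bl=60.0, weight_1yr=59.0, weight_2yr=65.0)
    t = classify_patient(next(make_cohort(rows).records()))
    assert t.pct_change_yr1 == pytest.approx(-100 / 60)
    assert t.pct_change_yr2 == pytest.approx(100 * 6 / 59)


def test_classify_patient_missing_weight_named():
    rows = make_rows(1, weight_1yr=np.nan)
    rec = next(make_cohort(rows).records())
    with pytest.raises(ValueError, match="weight_1yr"):
        classify_patient(rec)


def test_yr2_base_switch():
    rows = make_rows(1, weight_bl=60.0, weight_1yr=66.0, weight_2yr=66.5)
    rec = next(make_cohort(rows).records())
    t_int = classify_patient(rec, yr2_base="interval")
    t_bl = classify_patient(rec, yr2_base="baseline")
    assert t_int.pct_change_yr2 == pytest.approx(100 * 0.5 / 66)
    assert t_bl.pct_change_yr2 == pytest.approx(100 * 6.5 / 60)
    assert t_int.cat_yr2 is C.MAINTAIN
    assert t_bl.cat_yr2 is C.INCREASE_SEVERE


@settings(max_examples=100, derandomize=True)
@given(
    w=st.tuples(*([st.floats(min_value=30, max_value=150)] * 3)),
    scale=st.floats(min_value=0.1, max_value=10),
)
def test_scale_invariance(w, scale):
    """Multiplying all three weights by a constant keeps the profile."""
    rows = make_rows(1, weight_bl=w[0], weight_1yr=w[1], weight_2yr=w[2])
    a = classify_patient(next(make_cohort(rows).records()))
    rows2 = make_rows(1, weight_bl=w[0] * scale, weight_1yr=w[1] * scale,
                      weight_2yr=w[2] * scale)
    b = classify_patient(next(make_cohort(rows2).records()))
    assert (a.cat_yr1, a.cat_yr2, a.profile) == (b.cat_yr1, b.cat_yr2, b.profile)


def test_classify_cohort_matches_scalar(tiny_cohort):
    table = classify_cohort(tiny_cohort)
    for rec, (_, row) in zip(tiny_cohort.records(), table.iterrows()):
        t = classify_patient(rec)
        assert row["cat_yr1"] == t.cat_yr1.value
        assert row["cat_yr2"] == t.cat_yr2.value
        assert row["profile"] == t.profile.value
        assert row["pct_yr1"] == pytest.approx(t.pct_change_yr1)


def test_cross_tab_empty_and_conservation(rng):
    empty = cross_tabulate(pd.DataFrame(columns=["cat_yr1", "cat_yr2"]))
    assert empty.grand_total == 0
    assert (empty.counts.to_numpy() == 0).all()
    totals = profile_totals(empty)
    assert (totals["count"] == 0).all() and totals["pct"].isna().all()

    # random tables conserve counts across marginals and profiles
    order = [c.value for c in CATEGORY_ORDER]
    for _ in range(20):
        n = int(rng.integers(1, 200))
        df = pd.DataFrame({
            "cat_yr1": rng.choice(order, n),
            "cat_yr2": rng.choice(order, n),
        })
        tab = cross_tabulate(df)
        assert tab.grand_total == n
        assert tab.row_totals.sum() == n
        assert tab.col_totals.sum() == n
        assert profile_totals(tab)["count"].sum() == n


def test_reference_crosstab_replay():
    """The published 16 cell counts aggregate to the published profile
    membership counts; grand total 391, first-row marginal 269."""
    tab = reference_crosstab()
    assert tab.grand_total == 391
    assert int(tab.row_totals.iloc[0]) == 269
    totals = profile_totals(tab).set_index("profile")
    assert totals.loc["super_high_risk", "count"] == 151
    assert totals.loc["high_risk_mitigated", "count"] == 133
    assert totals.loc["at_risk", "count"] == 17
    assert totals.loc["delayed_risk", "count"] == 34
    assert totals.loc["low_risk", "count"] == 56
    assert totals.loc["super_high_risk", "pct"] == 38.6
    assert totals.loc["high_risk_mitigated", "pct"] == 34.0
    assert totals.loc["at_risk", "pct"] == 4.3


def test_single_patient_profile_totals():
    df = pd.DataFrame({"cat_yr1": ["maintain"], "cat_yr2": ["maintain"]})
    totals = profile_totals(cross_tabulate(df)).set_index("profile")
    assert totals.loc["low_risk", "count"] == 1
    assert totals.loc["low_risk", "pct"] == 100.0
    assert totals.drop("low_risk")["count"].sum() == 0


def test_round_half_up_ties():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(8.65, 1) == 8.7
    assert round_half_up(-0.25, 1) == -0.3
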