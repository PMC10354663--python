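import numpy as np
import pandas as pd
import pytest

from weighttraj.cohort import COLUMNS, Cohort, make_cohort

BASE_ROW = {
    "id": "P1",
    "age_baseline": 25.0,
    "sex": "female",
    "education": "below_tertiary",
    "vocational_baseline": "occupied",
    "vocational_2yr": "occupied",
    "dup_months": 10.0,
    "admissions": "one",
    "panss_total_bl": 84.0,
    "panss_positive_bl": 23.0,
    "panss_negative_bl": 19.0,
    "panss_general_bl": 42.0,
    "panss_total_2yr": 43.0,
    "panss_positive_2yr": 9.0,
    "panss_negative_2yr": 11.0,
    "panss_general_2yr": 23.0,
    "gaf_bl": 42.0,
    "gaf_2yr": 71.0,
    "height_m": 1.65,
    "weight_bl": 60.0,
    "weight_1yr": 66.0,
    "weight_2yr": 72.0,
}


def make_rows(n=1, **overrides):
    """Build n valid cohort rows; overrides may be scalars or lists."""
    rows = []
    for i in range(n):
        row = dict(BASE_ROW)
        row["id"] = f"P{i + 1}"
        for k, v in overrides.items():
            row[k] = v[i] if isinstance(v, (list, tuple)) else v
        rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


@pytest.fixture
def tiny_cohort() -> Cohort:
    df = make_rows(3, weight_1yr=[66.0, 60.0, 59.0], weight_2yr=[72.0, 60.0, 65.0])
    return make_cohort(df, provenance="fixture")


@pytest.fixture
def rng():
    return np.random.default_rng(20240391)
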