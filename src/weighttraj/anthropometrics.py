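"""BMI computation and the Asia-Pacific WHO classification.

Bands (kg/m^2, lower-inclusive): underweight <18.5, normal 18.5-<23,
overweight 23-<25, obese >=25.  No rounding is applied before banding.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

__all__ = ["BMICategory", "bmi", "bmi_category", "add_bmi_columns"]


class BMICategory(str, Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


#: Band ordering, lowest BMI first.
BAND_ORDER = [
    BMICategory.UNDERWEIGHT,
    BMICategory.NORMAL,
    BMICategory.OVERWEIGHT,
    BMICategory.OBESE,
]


def bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index, weight / height^2."""
    if not (weight_kg > 0 and height_m > 0):
        raise ValueError(
            f"weight and height must be positive, got {weight_kg}, {height_m}"
        )
    return weight_kg / height_m**2


def bmi_category(b: float) -> BMICategory:
    """Asia-Pacific WHO band for a positive BMI value."""
    if not b > 0:
        raise ValueError(f"BMI must be positive, got {b}")
    if b >= 25.0:
        return BMICategory.OBESE
    if b >= 23.0:
        return BMICategory.OVERWEIGHT
    if b >= 18.5:
        return BMICategory.NORMAL
    return BMICategory.UNDERWEIGHT


def add_bmi_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append bmi_bl / bmi_2yr and their bands to a per-patient table.

    Expects height_m, weight_bl and weight_2yr columns; missing weights
    yield missing BMI and band.
    """
    out = table.copy()
    h2 = out["height_m"].astype(float) ** 2
    for when in ("bl", "2yr"):
        b = out[f"weight_{when}"].astype(float) / h2
        out[f"bmi_{when}"] = b
        out[f"bmi_band_{when}"] = [
            bmi_category(v).value if np.isfinite(v) else None for v in b
        ]
    return out
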