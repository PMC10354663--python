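"""Synthetic first-episode-psychosis cohort generator.

Emulates the statistical structure the pipeline assumes: published
marginal distributions for demographics, PANSS/GAF scores and body
weight; a 16-cell mixture over (year-1, year-2) weight-change category
pairs; injectable profile effects on 2-year outcomes; and a logistic
missing-not-at-random mechanism on the weight fields driven by sex,
age, education and duration of untreated psychosis.

Weights are reconstructed multiplicatively from the drawn percentage
changes (w1 = w0*(1+p1/100)), so with missingness disabled the
trajectory classifier is an exact inverse of the generator.  One
seeded generator drives all draws in a fixed, documented order
(covariates, trajectory cell, percent changes, outcomes, missingness),
so a seed fully determines the cohort.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .cohort import CLINICAL_FIELDS, COLUMNS, Cohort
from .trajectory import (
    CATEGORY_ORDER,
    REFERENCE_CROSSTAB_COUNTS,
    ChangeCategory,
    assign_profile,
)

__all__ = [
    "MissingnessModel",
    "ProfileEffects",
    "GeneratorConfig",
    "generate_cohort",
    "summarize_cohort",
]

# margin keeping drawn percent changes strictly inside their category
# band, so float round-trip through weights cannot flip a category
_EDGE = 1e-6


@dataclass
class MissingnessModel:
    """Log-odds model for missing >= 1 weight (MNAR on covariates)."""

    intercept: float = -2.1
    male: float = 0.5
    age_per_year: float = 0.03
    tertiary: float = 0.6
    dup_per_month: float = 0.01
    enabled: bool = True


@dataclass
class ProfileEffects:
    """Additive shifts injected on 2-year outcomes for one profile."""

    panss_total_2yr: float = 0.0
    gaf_2yr: float = 0.0
    vocational_logodds: float = 0.0


def _default_effects() -> dict[str, ProfileEffects]:
    # delayed-risk patients fare worst at 2 years (higher symptoms,
    # lower functioning); other profiles carry no injected effect
    return {"delayed_risk": ProfileEffects(panss_total_2yr=8.0, gaf_2yr=-6.0)}


@dataclass
class GeneratorConfig:
    """All knobs of the generator; defaults reproduce the published
    cohort regime (n=391 complete-data mixture, published marginals)."""

    n: int = 391
    # 4x4 cell probabilities (rows year-1 category, cols year-2), in
    # CATEGORY_ORDER; default = published cross-tab counts / 391
    cell_probs: np.ndarray = field(
        default_factory=lambda: REFERENCE_CROSSTAB_COUNTS / REFERENCE_CROSSTAB_COUNTS.sum()
    )
    # percent-change draw bands: severe tail cap and decrease cap (%)
    severe_cap: float = 45.0
    decrease_cap: float = -20.0
    # anthropometrics
    weight_bl_mean: float = 60.0
    weight_bl_sd: float = 16.0
    weight_bl_bounds: tuple[float, float] = (35.0, 130.0)
    height_by_sex: dict = field(
        default_factory=lambda: {"male": (1.71, 0.06), "female": (1.60, 0.06)}
    )
    # demographics
    p_male: float = 0.494
    p_tertiary: float = 0.522
    p_occupied_bl: float = 0.517
    p_occupied_2yr: float = 0.621
    admissions_probs: tuple[float, float, float] = (0.233, 0.332, 0.435)
    age_mean: float = 25.8
    age_sd: float = 6.7
    age_bounds: tuple[float, float] = (16.0, 65.0)
    dup_mean: float = 14.4
    dup_sd: float = 22.3
    dup_max: float = 240.0
    # PANSS baseline subscales (mean, sd, low, high); total = sum
    panss_bl: dict = field(
        default_factory=lambda: {
            "positive": (22.8, 6.0, 7.0, 49.0),
            "negative": (19.0, 8.6, 7.0, 49.0),
            "general": (42.4, 12.4, 16.0, 112.0),
        }
    )
    # 2-year PANSS total: mean, baseline-linkage slope, residual SD
    panss_2yr_mean: float = 42.7
    panss_2yr_slope: float = 0.35
    panss_2yr_noise_sd: float = 11.0
    # 2-year subscales as fixed fractions of the total plus noise
    panss_2yr_fractions: dict = field(
        default_factory=lambda: {"positive": 0.215, "negative": 0.265, "general": 0.520}
    )
    panss_2yr_subscale_noise_sd: float = 1.5
    gaf_bl_mean: float = 42.6
    gaf_bl_sd: float = 12.2
    gaf_2yr_mean: float = 71.4
    gaf_2yr_slope: float = 0.3
    gaf_2yr_noise_sd: float = 8.0
    profile_effects: dict = field(default_factory=_default_effects)
    missingness: MissingnessModel = field(default_factory=MissingnessModel)
    clinical_missing_rate: float = 0.0143  # per required clinical field

    def __post_init__(self) -> None:
        self.cell_probs = np.asarray(self.cell_probs, dtype=float)
        if self.cell_probs.shape != (4, 4):
            raise ValueError("cell_probs must be 4x4")
        if (self.cell_probs < 0).any() or not np.isclose(self.cell_probs.sum(), 1.0):
            raise ValueError("cell_probs must be non-negative and sum to 1")
        for name in ("weight_bl_sd", "age_sd", "dup_sd", "gaf_bl_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.clinical_missing_rate < 1:
            raise ValueError("clinical_missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_probs"] = self.cell_probs.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "missingness" in d and isinstance(d["missingness"], dict):
            d["missingness"] = MissingnessModel(**d["missingness"])
        if "profile_effects" in d:
            d["profile_effects"] = {
                k: (ProfileEffects(**v) if isinstance(v, dict) else v)
                for k, v in d["profile_effects"].items()
            }
        for key in ("weight_bl_bounds", "age_bounds", "admissions_probs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "panss_bl" in d:
            d["panss_bl"] = {k: tuple(v) for k, v in d["panss_bl"].items()}
        if "height_by_sex" in d:
            d["height_by_sex"] = {k: tuple(v) for k, v in d["height_by_sex"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _trunc_normal(rng, mean, sd, low, high, size):
    # shift the parent location so the *truncated* mean equals `mean`
    loc = mean
    for _ in range(4):
        a, b = (low - loc) / sd, (high - loc) / sd
        loc += mean - truncnorm.mean(a, b, loc=loc, scale=sd)
    a, b = (low - loc) / sd, (high - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _category_band(cat: str, cfg: GeneratorConfig) -> tuple[float, float]:
    if cat == ChangeCategory.INCREASE_SEVERE.value:
        return (7.0 + _EDGE, cfg.severe_cap)
    if cat == ChangeCategory.INCREASE_MILD.value:
        return (1.0 + _EDGE, 7.0 - _EDGE)
    if cat == ChangeCategory.MAINTAIN.value:
        return (-1.0 + _EDGE, 1.0 - _EDGE)
    return (cfg.decrease_cap, -1.0 - _EDGE)


def generate_cohort(cfg: GeneratorConfig, seed: int) -> Cohort:
    """Draw a synthetic cohort; the seed fully determines the output.

    The returned :class:`~weighttraj.cohort.Cohort` carries a
    ``latent`` attribute: a DataFrame (id, cat_yr1, cat_yr2, profile)
    of the drawn trajectory cells before any missingness was applied.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n
    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    # --- covariates ------------------------------------------------
    male = rng.random(n) < cfg.p_male
    sex = np.where(male, "male", "female")
    tertiary = rng.random(n) < cfg.p_tertiary
    education = np.where(tertiary, "tertiary_and_above", "below_tertiary")
    voc_bl = np.where(rng.random(n) < cfg.p_occupied_bl, "occupied", "unemployed")
    admissions = rng.choice(["none", "one", "multiple"], size=n,
                            p=np.asarray(cfg.admissions_probs)
                            / np.sum(cfg.admissions_probs))
    age = _trunc_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_bounds, size=n)
    # lognormal DUP matched by moments to the configured mean/SD
    sigma2 = np.log1p((cfg.dup_sd / cfg.dup_mean) ** 2)
    mu = np.log(cfg.dup_mean) - sigma2 / 2
    dup = np.minimum(rng.lognormal(mu, np.sqrt(sigma2), size=n), cfg.dup_max)

    height = np.empty(n)
    for s, (hm, hs) in cfg.height_by_sex.items():
        m = sex == s
        height[m] = rng.normal(hm, hs, size=int(m.sum()))
    height = np.clip(height, 1.35, 2.1)

    panss_sub_bl = {}
    for sub, (m_, s_, lo, hi) in cfg.panss_bl.items():
        panss_sub_bl[sub] = _trunc_normal(rng, m_, s_, lo, hi, size=n)
    panss_total_bl = sum(panss_sub_bl.values())
    panss_bl_mean_total = sum(v[0] for v in cfg.panss_bl.values())
    gaf_bl = np.clip(rng.normal(cfg.gaf_bl_mean, cfg.gaf_bl_sd, size=n), 1, 100)

    # --- trajectory mixture ----------------------------------------
    flat = cfg.cell_probs.ravel()
    cell = rng.choice(16, size=n, p=flat)
    order = [c.value for c in CATEGORY_ORDER]
    cat1 = np.array([order[c // 4] for c in cell])
    cat2 = np.array([order[c % 4] for c in cell])
    profile = np.array(
        [assign_profile(a, b).value for a, b in zip(cat1, cat2)], dtype=object
    )

    p1 = np.empty(n)
    p2 = np.empty(n)
    u1, u2 = rng.random(n), rng.random(n)
    for cat in order:
        lo, hi = _category_band(cat, cfg)
        m = cat1 == cat
        p1[m] = lo + u1[m] * (hi - lo)
        m = cat2 == cat
        p2[m] = lo + u2[m] * (hi - lo)

    w0 = _trunc_normal(rng, cfg.weight_bl_mean, cfg.weight_bl_sd,
                       *cfg.weight_bl_bounds, size=n)
    w1 = w0 * (1 + p1 / 100.0)
    w2 = w1 * (1 + p2 / 100.0)

    # --- 2-year outcomes -------------------------------------------
    eff_panss = np.zeros(n)
    eff_gaf = np.zeros(n)
    eff_voc = np.zeros(n)
    for prof, eff in cfg.profile_effects.items():
        m = profile == prof
        eff_panss[m] = eff.panss_total_2yr
        eff_gaf[m] = eff.gaf_2yr
        eff_voc[m] = eff.vocational_logodds
    panss_total_2yr = (
        cfg.panss_2yr_mean
        + cfg.panss_2yr_slope * (panss_total_bl - panss_bl_mean_total)
        + eff_panss
        + rng.normal(0, cfg.panss_2yr_noise_sd, size=n)
    )
    panss_sub_2yr = {
        sub: frac * panss_total_2yr
        + rng.normal(0, cfg.panss_2yr_subscale_noise_sd, size=n)
        for sub, frac in cfg.panss_2yr_fractions.items()
    }
    gaf_2yr = np.clip(
        cfg.gaf_2yr_mean
        + cfg.gaf_2yr_slope * (gaf_bl - cfg.gaf_bl_mean)
        + eff_gaf
        + rng.normal(0, cfg.gaf_2yr_noise_sd, size=n),
        1, 100,
    )
    alpha = np.log(cfg.p_occupied_2yr / (1 - cfg.p_occupied_2yr))
    p_occ = 1 / (1 + np.exp(-(alpha + eff_voc)))
    voc_2yr = np.where(rng.random(n) < p_occ, "occupied", "unemployed")

    df = pd.DataFrame(
        {
            "id": ids,
            "age_baseline": age,
            "sex": sex,
            "education": education,
            "vocational_baseline": voc_bl,
            "vocational_2yr": voc_2yr,
            "dup_months": dup,
            "admissions": admissions,
            "panss_total_bl": panss_total_bl,
            "panss_positive_bl": panss_sub_bl["positive"],
            "panss_negative_bl": panss_sub_bl["negative"],
            "panss_general_bl": panss_sub_bl["general"],
            "panss_total_2yr": panss_total_2yr,
            "panss_positive_2yr": panss_sub_2yr["positive"],
            "panss_negative_2yr": panss_sub_2yr["negative"],
            "panss_general_2yr": panss_sub_2yr["general"],
            "gaf_bl": gaf_bl,
            "gaf_2yr": gaf_2yr,
            "height_m": height,
            "weight_bl": w0,
            "weight_1yr": w1,
            "weight_2yr": w2,
        },
        columns=COLUMNS,
    )

    # --- missingness (applied last) --------------------------------
    mm = cfg.missingness
    if mm.enabled:
        lp = (
            mm.intercept
            + mm.male * male
            + mm.age_per_year * age
            + mm.tertiary * tertiary
            + mm.dup_per_month * dup
        )
        p_miss = 1 / (1 + np.exp(-lp))
        flagged = rng.random(n) < p_miss
        which = rng.random((n, 3)) < 0.6
        which[~which.any(axis=1), 2] = True  # guarantee >= 1 weight lost
        for j, col in enumerate(["weight_bl", "weight_1yr", "weight_2yr"]):
            df.loc[flagged & which[:, j], col] = np.nan
    if cfg.clinical_missing_rate > 0:
        for col in CLINICAL_FIELDS:
            m = rng.random(n) < cfg.clinical_missing_rate
            df.loc[m, col] = np.nan

    cohort = Cohort(df, provenance=f"generate_cohort(seed={seed}, n={n})")
    cohort.latent = pd.DataFrame(
        {"id": ids, "cat_yr1": cat1, "cat_yr2": cat2, "profile": profile}
    )
    return cohort


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Cohort summary table: mean (SD) for continuous variables,
    level counts and percentages for categoricals."""
    df = cohort.df
    rows = []
    if len(df) == 0:
        return pd.DataFrame(columns=["variable", "level", "n", "mean", "sd", "pct"])
    continuous = [
        "age_baseline", "dup_months",
        "panss_total_bl", "panss_positive_bl", "panss_negative_bl",
        "panss_general_bl", "gaf_bl", "weight_bl",
        "panss_total_2yr", "panss_positive_2yr", "panss_negative_2yr",
        "panss_general_2yr", "gaf_2yr", "weight_2yr",
    ]
    categorical = ["sex", "education", "vocational_baseline",
                   "admissions", "vocational_2yr"]
    for var in continuous:
        x = df[var].dropna().astype(float)
        rows.append({"variable": var, "level": "", "n": int(len(x)),
                     "mean": x.mean() if len(x) else np.nan,
                     "sd": x.std(ddof=1) if len(x) > 1 else np.nan,
                     "pct": np.nan})
    for var in categorical:
        counts = df[var].value_counts(dropna=True)
        denom = counts.sum()
        for level, cnt in counts.items():
            rows.append({"variable": var, "level": level, "n": int(cnt),
                         "mean": np.nan, "sd": np.nan,
                         "pct": 100.0 * cnt / denom if denom else np.nan})
    return pd.DataFrame(rows)
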