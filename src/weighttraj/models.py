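"""Exploratory 2-year outcome models.

Linear (OLS) models of 2-year PANSS/GAF scores and a binary logistic
model of 2-year vocational status, each on trajectory-profile
membership (dummy-coded against a configurable reference, default
low_risk) plus the usual covariates: age, sex, education, duration of
untreated psychosis, inpatient admissions (reference "none"), baseline
PANSS total and baseline GAF.  Listwise deletion within each model;
the n actually used is reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .trajectory import TrajectoryProfile

__all__ = [
    "ModelSpec",
    "ModelFit",
    "DEFAULT_COVARIATES",
    "fit_outcome_model",
    "fit_vocational_model",
]

#: Covariates entering every model besides the trajectory profile.
DEFAULT_COVARIATES = [
    "age_baseline",
    "sex",
    "education",
    "dup_months",
    "admissions",
    "panss_total_bl",
    "gaf_bl",
]

_CATEGORICAL_TERMS = {
    "profile": "C(profile, Treatment(reference='{ref}'))",
    "sex": "C(sex)",
    "education": "C(education)",
    "admissions": "C(admissions, Treatment(reference='none'))",
    "vocational_baseline": "C(vocational_baseline)",
}


@dataclass
class ModelSpec:
    """Declarative model description."""

    outcome: str
    family: str = "linear"  # linear | binary_logistic
    predictors: list[str] = field(default_factory=lambda: ["profile"] + DEFAULT_COVARIATES)
    ref_profile: str = TrajectoryProfile.LOW_RISK.value

    def formula(self) -> str:
        terms = []
        for p in self.predictors:
            t = _CATEGORICAL_TERMS.get(p, p)
            terms.append(t.format(ref=self.ref_profile) if "{ref}" in t else t)
        return f"{self.outcome} ~ " + " + ".join(terms)


@dataclass
class ModelFit:
    """Fitted coefficient table plus fit summaries."""

    spec: ModelSpec
    table: pd.DataFrame  # term, estimate, se, statistic, p
    n_used: int
    rsquared: float | None = None
    loglik: float | None = None
    aic: float | None = None

    def coefficient(self, substring: str) -> pd.Series:
        """First coefficient row whose term contains ``substring``."""
        hit = self.table[self.table["term"].str.contains(substring, regex=False)]
        if hit.empty:
            raise KeyError(f"no coefficient matching {substring!r}")
        return hit.iloc[0]


def _check_rank(res) -> None:
    exog = res.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify offending columns via pivoted QR
        names = res.model.exog_names
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in range(len(diag))
               if diag[i] < 1e-8 * max(diag.max(), 1.0)]
        raise ValueError(f"rank-deficient design; collinear term(s): {bad}")


_TERM_CLEANUP = re.compile(r"C\((\w+)(?:, Treatment\(reference='[^']*'\))?\)")


def _clean_term(term: str) -> str:
    """``C(profile, Treatment(reference='low_risk'))[T.at_risk]`` ->
    ``profile[T.at_risk]``."""
    return _TERM_CLEANUP.sub(r"\1", term)


def _coef_table(res) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [_clean_term(t) for t in res.params.index],
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "statistic": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    ).reset_index(drop=True)


def fit_outcome_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a declared outcome model on a classified cohort table.

    ``data`` must contain the outcome, a ``profile`` column, and every
    covariate; rows with any missing value among them are dropped
    (listwise within the model).
    """
    cols = [spec.outcome] + [p for p in spec.predictors]
    use = data[cols].dropna()
    n = len(use)
    if spec.family == "binary_logistic":
        y = use[spec.outcome]
        if y.nunique() < 2:
            raise ValueError(
                f"degenerate outcome: all {n} values of '{spec.outcome}' identical"
            )
        model = smf.logit(spec.formula(), data=use)
        try:
            with np.errstate(all="ignore"):
                res = model.fit(disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError) as e:
            raise ValueError(
                f"logistic fit failed (separation or singular design): {e}"
            ) from e
        if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 1e3:
            raise ValueError(
                "quasi-separation: some coefficients diverged "
                f"(max |beta| = {np.abs(res.params).max():.3g})"
            )
        _check_rank(res)
        return ModelFit(spec, _coef_table(res), n,
                        loglik=float(res.llf), aic=float(res.aic))
    elif spec.family == "linear":
        res = smf.ols(spec.formula(), data=use).fit()
        _check_rank(res)
        return ModelFit(spec, _coef_table(res), n, rsquared=float(res.rsquared))
    raise ValueError(f"unknown family {spec.family!r}")


def fit_vocational_model(data: pd.DataFrame,
                         ref_profile: str = TrajectoryProfile.LOW_RISK.value,
                         predictors: list[str] | None = None) -> ModelFit:
    """Logistic model of 2-year vocational status (occupied = 1)."""
    df = data.copy()
    df["vocational_2yr_occupied"] = df["vocational_2yr"].map(
        {"occupied": 1.0, "unemployed": 0.0}
    )
    spec = ModelSpec(
        outcome="vocational_2yr_occupied",
        family="binary_logistic",
        predictors=predictors or ["profile"] + DEFAULT_COVARIATES,
        ref_profile=ref_profile,
    )
    return fit_outcome_model(spec, df)
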