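#!/usr/bin/env python
"""Exploratory 2-year outcome models.

Fits, on the classified analysis set: OLS models of 2-year PANSS total
and GAF disability on trajectory-profile membership (reference:
low_risk) plus covariates, and a binary logistic model of 2-year
vocational status.  Under the default generator the delayed-risk
profile carries a +8 shift on the 2-year PANSS total and a -6 shift on
GAF, so those dummies should be the clearly non-null ones.
"""

import argparse
from pathlib import Path

from weighttraj.cohort import filter_complete_clinical, filter_complete_weight, read_cohort
from weighttraj.models import ModelSpec, fit_outcome_model, fit_vocational_model
from weighttraj.trajectory import classify_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort.csv")
    ap.add_argument("--ref-profile", default="low_risk")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    complete, _ = filter_complete_weight(cohort)
    analysed = filter_complete_clinical(complete)
    traj = classify_cohort(analysed)
    data = analysed.df.merge(traj[["id", "profile"]], on="id")

    for outcome in ("panss_total_2yr", "gaf_2yr"):
        fit = fit_outcome_model(
            ModelSpec(outcome=outcome, family="linear",
                      ref_profile=args.ref_profile),
            data,
        )
        fit.table.to_csv(RESULTS / f"model_{outcome}.csv", index=False)
        print(f"\n{outcome} (OLS, n={fit.n_used}, R^2={fit.rsquared:.3f}):")
        print(fit.table.to_string(index=False,
                                  float_format=lambda v: f"{v:.4f}"))

    voc = fit_vocational_model(data, ref_profile=args.ref_profile)
    voc.table.to_csv(RESULTS / "model_vocational_2yr.csv", index=False)
    print(f"\nvocational_2yr (logit, n={voc.n_used}, AIC={voc.aic:.1f}):")
    print(voc.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
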