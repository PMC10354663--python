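#!/usr/bin/env python
"""Classify 2-year weight trajectories for the analysis set.

Reads results/cohort.csv (run 01_simulate_cohort.py first), keeps
patients with complete weight and clinical data, computes yearly
percentage weight changes, categories and risk profiles, and writes
the per-patient trajectory table, the 4x4 cross-tabulation with
profile labels, profile membership totals, BMI bands at baseline and
2 years, and the cohort summary table.
"""

import argparse
from pathlib import Path

from weighttraj.anthropometrics import add_bmi_columns
from weighttraj.cohort import filter_complete_clinical, filter_complete_weight, read_cohort
from weighttraj.simulate import summarize_cohort
from weighttraj.trajectory import classify_cohort, cross_tabulate, profile_totals

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort.csv")
    ap.add_argument("--yr2-base", choices=["interval", "baseline"],
                    default="interval")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    complete, _ = filter_complete_weight(cohort)
    analysed = filter_complete_clinical(complete)
    print(f"analysis set: {len(analysed)} of {len(cohort)} patients")

    traj = classify_cohort(analysed, yr2_base=args.yr2_base)
    traj_out = traj.merge(
        analysed.df[["id", "height_m", "weight_bl", "weight_2yr"]], on="id"
    )
    traj_out = add_bmi_columns(traj_out)
    traj_out.to_csv(RESULTS / "trajectories.csv", index=False)

    tab = cross_tabulate(traj)
    tab.to_report_frame().to_csv(RESULTS / "crosstab.csv", index=False)
    totals = profile_totals(tab)
    totals.to_csv(RESULTS / "profile_totals.csv", index=False)
    summarize_cohort(analysed).to_csv(RESULTS / "cohort_summary.csv", index=False)

    print("\nprofile membership:")
    print(totals.to_string(index=False))
    bands = traj_out["bmi_band_2yr"].value_counts()
    print("\nBMI bands at 2 years (Asia-Pacific WHO):")
    print(bands.to_string())


if __name__ == "__main__":
    main()
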