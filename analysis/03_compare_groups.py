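#!/usr/bin/env python
"""Between-group comparison battery.

Three comparisons on results/cohort.csv: (1) baseline characteristics
of patients with vs without complete 2-year weight data (the MNAR
mechanism should leave the missing group more male, older, more
tertiary-educated, with longer untreated psychosis); (2) all variables
across the four first-year change categories (ANOVA / chi-square);
(3) among severe first-year gainers, continued gainers vs the rest.
"""

import argparse
from pathlib import Path

from weighttraj.cohort import filter_complete_clinical, filter_complete_weight, read_cohort
from weighttraj.stats import (
    compare_continued_gainers,
    compare_missingness,
    compare_yr1_groups,
    results_to_frame,
)
from weighttraj.trajectory import classify_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def _report(name: str, results) -> None:
    frame = results_to_frame(results)
    frame.to_csv(RESULTS / f"{name}.csv", index=False)
    print(f"\n{name}:")
    cols = ["variable", "test", "statistic", "df", "p"]
    print(frame[cols].to_string(index=False,
                                float_format=lambda v: f"{v:.4f}"))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort.csv")
    ap.add_argument("--continued-split", choices=["any_gain", "severe_only"],
                    default="any_gain")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    complete, _ = filter_complete_weight(cohort)
    analysed = filter_complete_clinical(complete)
    traj = classify_cohort(analysed)

    _report("compare_missingness", compare_missingness(cohort))
    _report("compare_yr1_groups", compare_yr1_groups(analysed, traj))
    _report("compare_continued_gainers",
            compare_continued_gainers(analysed, traj,
                                      split=args.continued_split))


if __name__ == "__main__":
    main()
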