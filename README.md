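# weighttraj

Rule-based classification of 2-year body-weight trajectories in
first-episode psychosis (FEP) cohorts, with the surrounding cohort
analytics: completeness filtering, missing-data comparisons, BMI
banding, between-group test batteries, exploratory outcome regressions,
and a synthetic-cohort generator so the entire pipeline runs without
access to any patient database.

## The problem and the method

Most patients starting antipsychotic treatment gain weight, but not on
a single schedule: some gain heavily in the first year and keep
gaining, some gain early and then stabilise, some only start gaining in
the second year. Distinguishing these courses matters clinically —
late gainers can be missed by first-year monitoring.

The classification is deliberately simple and auditable. For each
yearly interval the percentage weight change
`100 · (w_end − w_start) / w_start` is banded into four categories,
using the conventional ≥7% threshold for clinically significant gain:

| category        | band            |
|-----------------|-----------------|
| increase severe | gain ≥ 7%       |
| increase mild   | 1% < gain < 7%  |
| maintain        | −1% ≤ change ≤ 1% |
| decrease        | loss > 1%       |

The ordered pair (year-1 category, year-2 category) is then mapped
through an explicit 4×4 grouping matrix onto one of five named 2-year
risk profiles: **super high risk** (severe gain that starts in year 1
and continues), **high risk mitigated** (severe year-1 gain that stops),
**at risk** (sustained mild gain), **delayed risk** (gain that only
starts in year 2), and **low risk** (everything else). BMI is banded
with the Asia-Pacific WHO cutoffs (18.5 / 23 / 25 kg/m²).

Around the classifier the package implements the standard cohort
workflow: Student's pooled-variance t, Pearson χ² (no continuity
correction) and one-way ANOVA batteries for group comparisons; OLS and
binary-logistic models of 2-year PANSS, GAF and vocational outcomes on
profile membership plus covariates; and a seeded generator producing
cohorts with realistic marginals, a configurable 16-cell trajectory
mixture, injectable profile effects, and a logistic
missing-not-at-random (MNAR) mechanism on the weight fields.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_classify_trajectories.py
```

prints

```
simulated 686 patients -> results/cohort.csv
  complete weight data : 458 (66.8%)
  complete clinical too: 404 (88.2% of complete-weight)
analysis set: 404 of 686 patients

profile membership:
            profile  count  pct
    super_high_risk    162 40.1
high_risk_mitigated    142 35.1
            at_risk     14  3.5
       delayed_risk     31  7.7
           low_risk     55 13.6
```

i.e. the MNAR mechanism removes about a third of patients at the
weight-completeness filter, and of the 404 analysable patients roughly
40% gained severely in both years (super high risk) while ~8% only
began gaining in year 2 (delayed risk). `analysis/03_compare_groups.py`
then shows the missing-weight stratum is significantly more male,
older, more tertiary-educated and has longer untreated psychosis
(the injected MNAR directions), and `analysis/04_outcome_models.py`
recovers the injected delayed-risk shifts on the 2-year PANSS total
and GAF scores.

The same stages are available as a CLI
(`weighttraj simulate|classify|compare|model|analyze|replay-reference`)
and as library functions (`weighttraj.classify_cohort`,
`weighttraj.cross_tabulate`, ...).

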