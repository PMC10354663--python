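# Methods

## Trajectory classification

For a patient with weights `w0, w1, w2` (kg) at baseline, 1 year and
2 years, the two interval changes are `p1 = 100·(w1−w0)/w0` and
`p2 = 100·(w2−w1)/w1`. The denominator of the second interval is the
**1-year weight**, not baseline: the categories are defined per
interval and the cross-tabulation axes are "baseline → 1 yr" and
"1 yr → 2 yr". Because reasonable readers could take the second
percentage relative to baseline instead, `classify_patient` /
`classify_cohort` expose `yr2_base={"interval","baseline"}`; all
shipped defaults and tests use `interval`.

Banding uses the printed inequalities literally — gain ≥7 severe,
1 < gain < 7 mild, |change| ≤ 1 maintain, loss >1 decrease — with
exact floating-point comparisons on the unrounded percentage. No
pre-rounding: a change of 6.96% is *mild*, even though it would print
as 7.0%. The four predicates partition the real line (property-tested
over 10⁶ values including the boundary points −1, 1, 7).

The five-profile map is stored as an explicit 16-entry table rather
than derived from rules, because narrative descriptions ("severe then
decrease", "maintain then severe", …) under-determine several cells:
for example, *mild → maintain* is low risk while *maintain → mild* is
delayed risk, an asymmetry no simple rule produces. Reported
percentages are rounded half-up to 1 decimal (the convention of
clinical tables); counts are never rounded.

## BMI

`bmi = weight/height²` with the Asia-Pacific WHO bands, lower-inclusive:
underweight <18.5, normal [18.5, 23), overweight [23, 25), obese ≥25
kg/m². Heights read from CSV above 3 are treated as centimetres and
divided by 100 (the only unit heuristic in the package).

## Comparison battery

* Two-group continuous: pooled-variance Student's t (`scipy`
  `ttest_ind(equal_var=True)`), df = n₁+n₂−2 computed on
  pairwise-complete cases per variable. The pooled (not Welch) variant
  is used because the degrees of freedom it reports are the ones this
  style of cohort table prints.
* Categorical: Pearson χ² without continuity correction; expected
  counts below 5 are logged as warnings, not fatal.
* More than two groups: one-way ANOVA, df = (k−1, N−k).

Missing values are dropped pairwise per variable, never listwise
across the battery; a variable whose strata cannot support its test
(<2 cases in a group, degenerate table, zero pooled variance) is
returned flagged `computable=False` rather than raising, so one bad
variable never kills a battery. No multiple-testing correction is
applied by default, matching the descriptive α = 0.05 convention of
this literature.

"Continued to gain" among severe first-year gainers defaults to a
year-2 category of severe **or** mild (`split="any_gain"`);
`"severe_only"` is available because the narrower reading is equally
defensible.

## Outcome models

OLS for continuous 2-year outcomes (PANSS total, GAF), maximum
likelihood logit for 2-year vocational status (occupied = 1), both via
statsmodels formulas. Profile enters as four dummies against a
configurable reference (default `low_risk`; contrasts can be re-based
by re-fitting); admissions as two dummies against `none`. Listwise
deletion within each model, with the n actually used reported.
Rank-deficient designs raise an error naming the collinear terms
(pivoted-QR diagnostic); complete or quasi-separation in the logit
(non-finite standard errors or |β| > 10³) raises instead of returning
garbage.

## Synthetic cohort generator

The generator emulates the *statistical shape* the analysis assumes,
not any real patient population:

* **Demographics / clinical marginals** (defaults): 49.4% male; 52.2%
  tertiary education; 51.7% occupied at baseline, 62.1% at 2 years;
  admissions none/one/multiple = 23.3/33.2/43.5%; age ~ truncated
  normal 25.8 (6.7) on [16, 65]; DUP ~ lognormal moment-matched to
  mean 14.4, SD 22.3 months (right-skew follows from SD > mean),
  capped at 240; PANSS baseline subscales truncated normals
  (positive 22.8 (6), negative 19 (8.6), general 42.4 (12.4)) with
  total = their sum; GAF baseline 42.6 (12.2) clipped to [1, 100];
  baseline weight truncated normal 60 (16) kg on [35, 130]; height
  normal by sex (1.71/1.60 m, SD 0.06). Truncated normals shift the
  parent location so the *realized* mean equals the configured one.
* **Trajectory mixture**: each patient's (year-1, year-2) category
  pair is drawn from a 16-cell multinomial (default: the published
  cross-tab proportions, n = 391 regime). Percent changes are drawn
  uniformly inside the drawn category's band — severe on
  (7, +45]%, decrease on [−20, −1)% by default, the caps making the
  observed extreme gainers (+40% and beyond) representable — with a
  10⁻⁶ interior margin so float round-trips through reconstructed
  weights can never flip a category. Weights are rebuilt
  multiplicatively (`w1 = w0·(1+p1/100)`), making the classifier an
  exact inverse of the generator when missingness is off (tested at
  n = 10,000).
* **Outcomes**: 2-year PANSS total = 42.7 + 0.35·(baseline − 84.2) +
  profile effect + N(0, 11); its subscales are fixed fractions of the
  total plus small noise (so additivity holds only approximately —
  deliberate, since the schema treats subscale additivity as a warning
  at most). GAF 2-year = 71.4 + 0.3·(baseline − 42.6) + effect +
  N(0, 8), clipped to [1, 100]. Vocational status is Bernoulli on a
  logit with base rate 62.1% plus a per-profile log-odds shift.
  Default injected effects give delayed-risk patients +8 PANSS-total
  and −6 GAF points at 2 years (the direction this field reports for
  late gainers; magnitudes are this package's choice of a clearly
  detectable, clinically plausible signal).
* **Missingness**: applied last. Pr(missing ≥1 weight) is logistic in
  male (+0.5), age (+0.03/yr), tertiary education (+0.6) and DUP
  (+0.01/mo) with intercept −2.1, giving ≈35% marginal missingness and
  the over-representation of male/older/educated/long-DUP patients in
  the missing stratum. Flagged patients lose each weight with
  probability 0.6 (at least one guaranteed). Clinical fields are
  missing independently at 0.0143 per field, so ≈0.986⁹ ≈ 88% of
  weight-complete records survive the clinical filter — reproducing
  the 686 → ~445 → ~391 funnel shape.
* **Determinism**: one `numpy.random.default_rng(seed)` stream drives
  everything in a fixed draw order (covariates → mixture cell →
  percent changes → weights → outcomes → missingness); a seed fully
  determines the cohort, byte-for-byte through CSV round-trips.

What the generator does **not** model: correlations among covariates
(independent by default; inject via config if needed), pharmacology,
diet or activity, any height–weight correlation (so BMI band
*proportions* are not calibrated — only the weight-change machinery
is), and serial correlation in PANSS subscales beyond their shared
total. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its tests under a known data-generating
process — not fidelity of any particular real cohort's BMI
distribution.

## Numerical and design choices

* Percent categorization: exact comparisons, no tolerance; the
  boundary values 7, 1, −1 belong to severe, maintain, maintain.
* Table percentages: decimal half-up rounding at 1 d.p.
* Cross-tab: zero-count categories are kept as explicit zero
  rows/columns; an empty input yields an all-zero table with
  undefined (missing) percentages.
* "Complete clinical data" = education, both vocational statuses,
  DUP, admissions, PANSS totals and GAF at both time points (9
  fields); PANSS subscales are not required because no main analysis
  uses them.
* CSV is the sole cohort format (RFC-4180, UTF-8, header row; empty
  or "NA" cells are missing); the column dictionary is in
  `docs/cohort_schema.md`.

## Problem sizes

The shipped analyses and tests use: a 686-patient intake cohort
(01–04), n = 10,000 for the generator/classifier inversion check,
200 × n = 391 replicates for mixture recovery, 1000 × n = 2000
replicates for null calibration of the year-1 battery, and
400 × n = 1000 replicates for effect recovery and CI coverage —
sizes at which the binomial/multinomial error bounds used by the
tests are sharp enough to be informative while the whole suite runs
in about a minute and a half.

## Known limitations

* The classifier is a deterministic rule, not a model: no uncertainty
  attaches to a patient's profile, and measurement error in single
  weighings propagates directly (a 1-kg error on 60 kg is 1.7%, larger
  than the maintain band's half-width).
* Weight-change categories use two yearly snapshots; within-year
  dynamics are invisible by construction.
* The two printed membership percentages for delayed risk and low
  risk in the source tables are arithmetically inconsistent with
  their own counts by 0.1 (see `profile_totals`' recomputed values);
  this package reports the recomputed values.
* No imputation and no model-based (growth-mixture) trajectory
  estimation; both are out of scope.
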