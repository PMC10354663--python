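# Cohort CSV column dictionary

One row per patient; header row required; UTF-8, RFC-4180. Missing
values: empty cell or `NA` (case-insensitive). Categorical levels are
lowercase snake_case and closed (anything else is a validation error).

| column | type | levels / units | may be missing |
|---|---|---|---|
| id | string | unique per row | no |
| age_baseline | real | years, >0 | no |
| sex | categorical | male, female | no |
| education | categorical | tertiary_and_above, below_tertiary | yes |
| vocational_baseline | categorical | occupied, unemployed | yes |
| vocational_2yr | categorical | occupied, unemployed | yes |
| dup_months | real | months, ≥0 (duration of untreated psychosis) | yes |
| admissions | categorical | none, one, multiple | yes |
| panss_total_bl | real | PANSS total, baseline | yes |
| panss_positive_bl | real | PANSS positive, baseline | yes |
| panss_negative_bl | real | PANSS negative, baseline | yes |
| panss_general_bl | real | PANSS general psychopathology, baseline | yes |
| panss_total_2yr | real | PANSS total, 2-year | yes |
| panss_positive_2yr | real | PANSS positive, 2-year | yes |
| panss_negative_2yr | real | PANSS negative, 2-year | yes |
| panss_general_2yr | real | PANSS general psychopathology, 2-year | yes |
| gaf_bl | real | GAF disability, 0–100, baseline | yes |
| gaf_2yr | real | GAF disability, 0–100, 2-year | yes |
| height_m | real | metres; values >3 parsed as cm and divided by 100 | no |
| weight_bl | real | kg, >0 | yes |
| weight_1yr | real | kg, >0 | yes |
| weight_2yr | real | kg, >0 | yes |

Validation: unique ids; heights in (0.5, 2.5) m after unit
normalization; weights strictly positive when present. PANSS
additivity (total = positive + negative + general) is optionally
checked with a tolerance and warned about, never rejected.

"Complete weight data" = all of weight_bl, weight_1yr, weight_2yr
present. "Complete clinical data" = education, vocational_baseline,
vocational_2yr, dup_months, admissions, panss_total_bl,
panss_total_2yr, gaf_bl, gaf_2yr all present.
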