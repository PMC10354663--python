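# Default synthetic-cohort regime: published marginals and
# trajectory mixture, MNAR weight missingness, 686-patient intake.
n: 686
cell_probs:
- - 0.14578005115089515
  - 0.2020460358056266
  - 0.08695652173913043
  - 0.2531969309462916
- - 0.03836317135549872
  - 0.043478260869565216
  - 0.023017902813299233
  - 0.0741687979539642
- - 0.01278772378516624
  - 0.0076726342710997444
  - 0.0076726342710997444
  - 0.0076726342710997444
- - 0.04092071611253197
  - 0.02557544757033248
  - 0.0076726342710997444
  - 0.023017902813299233
severe_cap: 45.0
decrease_cap: -20.0
weight_bl_mean: 60.0
weight_bl_sd: 16.0
weight_bl_bounds:
- 35.0
- 130.0
height_by_sex:
  male:
  - 1.71
  - 0.06
  female:
  - 1.6
  - 0.06
p_male: 0.494
p_tertiary: 0.522
p_occupied_bl: 0.517
p_occupied_2yr: 0.621
admissions_probs:
- 0.233
- 0.332
- 0.435
age_mean: 25.8
age_sd: 6.7
age_bounds:
- 16.0
- 65.0
dup_mean: 14.4
dup_sd: 22.3
dup_max: 240.0
panss_bl:
  positive:
  - 22.8
  - 6.0
  - 7.0
  - 49.0
  negative:
  - 19.0
  - 8.6
  - 7.0
  - 49.0
  general:
  - 42.4
  - 12.4
  - 16.0
  - 112.0
panss_2yr_mean: 42.7
panss_2yr_slope: 0.35
panss_2yr_noise_sd: 11.0
panss_2yr_fractions:
  positive: 0.215
  negative: 0.265
  general: 0.52
panss_2yr_subscale_noise_sd: 1.5
gaf_bl_mean: 42.6
gaf_bl_sd: 12.2
gaf_2yr_mean: 71.4
gaf_2yr_slope: 0.3
gaf_2yr_noise_sd: 8.0
profile_effects:
  delayed_risk:
    panss_total_2yr: 8.0
    gaf_2yr: -6.0
    vocational_logodds: 0.0
missingness:
  intercept: -2.1
  male: 0.5
  age_per_year: 0.03
  tertiary: 0.6
  dup_per_month: 0.01
  enabled: true
clinical_missing_rate: 0.0143
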