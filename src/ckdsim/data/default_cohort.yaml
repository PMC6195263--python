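# Default synthetic-cohort specification.
#
# A stand-in for a US-adult (30+) survey cohort: every marginal below is a
# package-shipped placeholder loosely shaped like 2000s-era US adults, NOT a
# survey estimate.  All weights/prevalences are configurable; tools that run
# this spec print the resolved values so the cohort in use is always visible.

n: 10000
seed: 20100
age_band_weights: {"30-49": 0.45, "50-64": 0.33, "65-90": 0.22}
sex_split_female: 0.52
race_weights: {nh_white: 0.64, nh_black: 0.12, hispanic: 0.16, other: 0.08}
bmi_cat_weights_by_age_band:
  "30-49": {underweight: 0.020, normal: 0.320, overweight: 0.320, obesity: 0.340}
  "50-64": {underweight: 0.015, normal: 0.270, overweight: 0.345, obesity: 0.370}
  "65-90": {underweight: 0.020, normal: 0.300, overweight: 0.350, obesity: 0.330}
# Cross-sectional eGFR model: mean = intercept_age30 + slope_per_year*(age-30),
# residual SD as given, truncated to (5, 150].
egfr_age_model: {intercept_age30: 105.0, slope_per_year: -0.8, sd: 13.0}
# Mean excess BMI over 30 kg/m^2 in the obesity category (exponential tail).
obesity_bmi_scale: 4.5
# Baseline prevalence by age band (for the average BMI mix) ...
prevalence:
  diabetes:     {"30-49": 0.050, "50-64": 0.130, "65-90": 0.200}
  hypertension: {"30-49": 0.180, "50-64": 0.420, "65-90": 0.620}
  chd:          {"30-49": 0.010, "50-64": 0.050, "65-90": 0.120}
  stroke:       {"30-49": 0.005, "50-64": 0.025, "65-90": 0.070}
  mi:           {"30-49": 0.005, "50-64": 0.030, "65-90": 0.080}
  alb_moderate: {"30-49": 0.050, "50-64": 0.080, "65-90": 0.130}
  alb_severe:   {"30-49": 0.004, "50-64": 0.008, "65-90": 0.015}
# ... scaled by BMI-category multipliers (capped at probability 1).
bmi_prevalence_multipliers:
  diabetes:     {underweight: 0.5, normal: 0.5, overweight: 0.9, obesity: 1.7}
  hypertension: {underweight: 0.7, normal: 0.7, overweight: 1.0, obesity: 1.4}
  cvd:          {underweight: 0.9, normal: 0.9, overweight: 1.0, obesity: 1.2}
  albuminuria:  {underweight: 0.9, normal: 0.9, overweight: 1.0, obesity: 1.4}
# A single survey measurement of moderately increased albuminuria is retained
# as persistent with this probability (persistence-style adjustment).
albuminuria_retain_prob: 0.6
# Optional fraction of severe-albuminuria cases mapped to the heaviest
# proteinuria category (>=1.50 g/24h) instead of 0.50-1.49.
proteinuria_p4_fraction_severe: 0.0
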