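# Default parameter bundle for the CKD lifetime-risk microsimulation.
#
# `progression` and `obesity` carry the published slope coefficients and
# obesity relative risks / BMI drift values.  `background` tables (incidence,
# mortality, hazard ratios) and `progression.variance_multiplier_ge60` are
# package-shipped, NON-AUTHORITATIVE stand-ins chosen from public US
# epidemiology; see docs/methods.md before using them for anything beyond
# the shipped synthetic-cohort experiments.

progression:
  base_change: {lt60: 0.42, ge60: 0.33}
  coef_female: {lt60: -0.12, ge60: 0.14}
  coef_nh_black: {lt60: -0.61, ge60: -0.17}
  coef_hispanic: {lt60: -0.40, ge60: 0.37}
  coef_other: {lt60: -0.65, ge60: -0.28}
  coef_prot_p2: {lt60: -0.86, ge60: -0.26}
  coef_prot_p3: {lt60: -2.38, ge60: -1.05}
  coef_prot_p4: {lt60: -4.17, ge60: -4.56}
  coef_diabetes: {lt60: -0.29, ge60: -0.81}
  coef_hypertension: {lt60: -0.15, ge60: -0.29}
  coef_obesity: {lt60: 0.26, ge60: -0.15}
  sd_annual_change: {lt60: 1.64, ge60: 1.77}
  # Calibration factor on the ge60 variance term (sd scaled by its sqrt).
  # The published model calibrates this against an external cohort; the
  # value below is a configurable guess, not a published number.
  variance_multiplier_ge60: 0.5

obesity:
  rr_diabetes:
    overweight: {male: 1.0, female: 1.0}
    obesity: {male: 1.85, female: 1.36}
  rr_hypertension:
    overweight: {male: 1.48, female: 1.70}
    obesity: {male: 2.23, female: 2.63}
  rr_mi: {overweight: 1.0, obesity: 1.0}
  rr_chd: {overweight: 1.43, obesity: 1.58}
  rr_stroke: {overweight: 1.0, obesity: 1.0}
  bmi_delta:
    "30-49":
      white: {male: 0.23, female: 0.24}
      black: {male: 0.32, female: 0.41}
    "50+":
      white: {male: 0.073, female: 0.073}
      black: {male: 0.020, female: 0.020}
  # BMI drift is published for white/black groups only; hispanic and other
  # map to the white coefficients by default (override here if desired).
  race_to_bmi_group: {nh_white: white, nh_black: black, hispanic: white, other: white}

background:
  # 5-year bands from 30 to 90 (12 bands).  All values are annual
  # probabilities; every series must be non-decreasing in age.
  age_bands: [30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90]
  mortality:
    male:   [0.0014, 0.0018, 0.0025, 0.0038, 0.0057, 0.0085, 0.0125, 0.018, 0.028, 0.044, 0.072, 0.120]
    female: [0.0008, 0.0011, 0.0016, 0.0023, 0.0034, 0.0051, 0.0077, 0.0115, 0.018, 0.030, 0.051, 0.091]
  incidence:
    diabetes:
      male:   [0.003, 0.004, 0.006, 0.008, 0.010, 0.012, 0.013, 0.013, 0.013, 0.013, 0.013, 0.013]
      female: [0.003, 0.004, 0.006, 0.008, 0.010, 0.012, 0.013, 0.013, 0.013, 0.013, 0.013, 0.013]
    hypertension:
      male:   [0.010, 0.013, 0.017, 0.022, 0.028, 0.034, 0.040, 0.045, 0.050, 0.054, 0.057, 0.060]
      female: [0.010, 0.013, 0.017, 0.022, 0.028, 0.034, 0.040, 0.045, 0.050, 0.054, 0.057, 0.060]
    chd:
      male:   [0.0010, 0.0015, 0.0020, 0.0030, 0.0040, 0.0060, 0.0080, 0.0100, 0.0120, 0.0140, 0.0160, 0.0180]
      female: [0.0006, 0.0009, 0.0012, 0.0018, 0.0024, 0.0036, 0.0048, 0.0060, 0.0072, 0.0084, 0.0096, 0.0108]
    stroke:
      male:   [0.0005, 0.0007, 0.0010, 0.0015, 0.0020, 0.0030, 0.0040, 0.0060, 0.0080, 0.0110, 0.0140, 0.0180]
      female: [0.0005, 0.0007, 0.0010, 0.0015, 0.0020, 0.0030, 0.0040, 0.0060, 0.0080, 0.0110, 0.0140, 0.0180]
    mi:
      male:   [0.0006, 0.0009, 0.0012, 0.0018, 0.0024, 0.0036, 0.0048, 0.0060, 0.0072, 0.0084, 0.0096, 0.0108]
      female: [0.0004, 0.0005, 0.0007, 0.0011, 0.0014, 0.0022, 0.0029, 0.0036, 0.0043, 0.0050, 0.0058, 0.0065]
    # normal -> moderately increased albuminuria (before the diabetes /
    # hypertension multipliers below)
    albuminuria:
      male:   [0.0020, 0.0024, 0.0028, 0.0033, 0.0038, 0.0044, 0.0050, 0.0057, 0.0065, 0.0074, 0.0084, 0.0095]
      female: [0.0020, 0.0024, 0.0028, 0.0033, 0.0038, 0.0044, 0.0050, 0.0057, 0.0065, 0.0074, 0.0084, 0.0095]
    # moderately -> severely increased albuminuria
    albuminuria_severe:
      male:   [0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020]
      female: [0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020, 0.020]
  albuminuria_rr_diabetes: 3.0
  albuminuria_rr_hypertension: 1.5
  hr_mortality_by_stage: {none: 1.0, s1: 1.0, s2: 1.05, s3a: 1.2, s3b: 1.5, s4: 2.2, s5: 4.0}
  hr_mortality_cvd: 1.6

simulation:
  start_year: 2010
  max_age: 90
  bootstrap_reps: 100
  ci_percentiles: [2.5, 97.5]
  master_seed: 20181019
  deterministic_mode: false
  slope_redraw_policy: once_at_baseline
  pass_through_staging: true
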