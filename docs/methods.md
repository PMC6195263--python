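# Methods

`ckdsim` is an individual-level, annual-cycle microsimulation of chronic
kidney disease (CKD). Each simulated person carries age, sex,
race/ethnicity, eGFR, albuminuria category, proteinuria category, diabetes,
hypertension, CVD history (CHD, stroke, MI) and continuous BMI, and is
followed from a baseline age (30–90) until death or age 90. The state space
for kidney disease is: no CKD, stages 1–5 with stage 3 split into 3a/3b, and
death.

## eGFR trajectory model

The annual change in eGFR (ml/min/1.73 m²/yr) is

```
Δe_t = β0[b] + x_t'β[b] + ε
```

where `b ∈ {lt60, ge60}` is the **baseline** eGFR stratum (< 60 / ≥ 60,
frozen at simulation start — a person crossing 60 mid-course keeps the
baseline parameter column, mirroring the stratified estimation design), and
`x_t` holds the person's *current* indicators: female sex, race group,
proteinuria category (p2: 0.10–0.49, p3: 0.50–1.49, p4: ≥ 1.50 g/24 h),
diabetes, hypertension, and obesity (BMI ≥ 30). The coefficients are the
published mixed-effect estimates shipped in
`src/ckdsim/data/default_params.yaml`; they are taken as given and no
fitting machinery exists in this package.

`ε` is the residual draw. Under the default `once_at_baseline` policy it is
a person-level random slope, drawn once per person from Normal(0, sd[b])
and held for life, while the covariate part is recomputed every year as
conditions switch on. Persistent slopes concentrate risk in the tails,
which is what drives stage-4/5 attainment; an `annual_iid` policy (a fresh
ε every cycle) is available and produces much thinner tails. The residual
SD for the ≥ 60 stratum is multiplied by `sqrt(variance_multiplier_ge60)`.
**The multiplier is unanchored**: the original model calibrated this
variance against an external cohort whose raw data are not available here,
so it ships as a configurable default of 0.5 and results involving stage
4/5 tails are sensitive to it.

eGFR is floored at 1.0 ml/min/1.73 m² to avoid nonphysical values. Stages
are assigned each year from eGFR and kidney damage (albuminuria ≥
moderate): ≥ 90 with damage → s1, 60–89 with damage → s2, then 45–59 → s3a,
30–44 → s3b, 15–29 → s4, < 15 → s5 regardless of damage. Bands are
upper-exclusive. The highest attained stage is a ratchet, and with
`pass_through_staging` (default on) a year that skips GFR bands marks the
intermediate GFR-defined stages as attained, so sequential-stage
bookkeeping (3a before 3b before 4 before 5) holds across large drops.
Stage 5 is absorbing for the mortality hazard even if eGFR later drifts
back over the boundary. Stages 1–2 can be skipped entirely by persons who
never develop albuminuria.

## Obesity and comorbidity dynamics

BMI drifts deterministically each year by an age-band (30–49 / 50+) ×
race-group × sex increment; the published drift values exist for
white/black groups only, so hispanic and "other" map to the white
coefficients by default (configurable). The BMI category is recomputed
annually, so a normal-weight 35-year-old can become overweight or obese
mid-course and immediately picks up the corresponding relative risks and
slope coefficient.

Incident diabetes, hypertension, CHD, stroke and MI fire independently each
year with probability `min(1, base_rate(age, sex) × RR(bmi_cat, sex))`.
Risk-scale multiplication with a cap is exact for small probabilities and
monotone; it is an approximation to hazard-scale scaling. Relative risks of
1 (overweight→diabetes, MI, stroke) are stored explicitly so the ±25%
sensitivity machinery scales uniformly. All conditions are absorbing.

Albuminuria advances at most one level per year (normal → moderate →
severe). The normal→moderate rate is multiplied by configurable factors
when diabetes (default 3.0) or hypertension (default 1.5) is present —
without these the obesity → diabetes/hypertension → kidney-damage pathway
would not reach the any-CKD outcome, which is dominated by
albuminuria-defined stages 1–2; the defaults reflect the several-fold
excess of microalbuminuria incidence in diabetes. The proteinuria covariate
tracks albuminuria (normal→p1, moderate→p2, severe→p3; an optional fraction
of severe cases can be assigned p4) and never moves down.

Mortality each year is `life_table(age, sex) × HR(current stage) × HR(CVD
if any CVD flag)`. There is deliberately **no direct BMI term**: with full
adjustment the evidence base shows no obesity effect on non-CVD mortality,
so obesity reaches survival only through acquired CVD and CKD stage.

## Cycle order and bookkeeping

Within a year: mortality → BMI drift → incident conditions → eGFR step →
staging; then age increments. The order is a fixed global constant (the
original model does not publish its order; changing it shifts results
slightly, so it is not a knob). The start year 2010 is bookkeeping only —
no secular trends are modelled. Persons entering at the horizon age
simulate zero cycles and report their baseline stage.

Lifetime risk of any CKD counts persons whose highest attained stage is ≥ 1
— including those already in a CKD stage at baseline. Highest-stage shares
partition the any-CKD risk exactly.

## Randomness and reproducibility

Every person owns a counter-based Philox stream keyed by
`(master_seed << 64) + person_id`, from which a fixed layout of draws is
taken: eight uniform channels per cycle (mortality, five incident
conditions, two albuminuria transitions) and one standard normal per cycle
plus one at baseline. Results are therefore bit-reproducible, independent
of cohort order, and unchanged for person *i* by anything that happens to
person *j*. The synthetic-cohort generator likewise consumes a fixed number
of draws per attribute block, so two specs differing only in one marginal
(e.g. the BMI-category weights) yield cohorts identical in every other
column under the same seed — this is what makes seed-matched,
covariate-matched group comparisons exact.

## Synthetic cohort

The generator emulates a US-adult (30+) survey cohort: categorical draws
for age band, sex, race and BMI category; continuous BMI within the
category (uniform within band; an exponential tail with mean excess 4.5
kg/m² above 30 for obesity); eGFR from a truncated-normal cross-sectional
age model (mean 105 at age 30, −0.8/yr, SD 13, truncated to (5, 150]); and
baseline diabetes/hypertension/CVD/albuminuria prevalences by age band
scaled by BMI-category multipliers. A consistent serum-creatinine column is
emitted by closed-form inversion of the 2009 CKD-EPI creatinine equation,
so both input paths (eGFR directly, or creatinine → CKD-EPI) are exercised.
Observed moderate albuminuria is retained as persistent with probability
0.6 (a persistence-style adjustment standing in for an unpublished
algorithm; configurable).

Every default marginal is a package-shipped placeholder "loosely shaped
like US adults" — none is a survey estimate, and tools that run a spec
print the resolved values. What passing tests show is therefore that the
*mechanics* (distributional recovery, seeding, matched-stream contracts)
are correct, not that the cohort matches any real population; in
particular the joint structure of real survey data (correlated
eGFR/albuminuria/comorbidity within person, survey weights, measurement
error) is not emulated.

## Outcomes, bootstrap, sensitivity

Lifetime-risk tables report, per baseline BMI category (optionally × age
band), the any-CKD risk and the distribution of highest stage attained.
Confidence intervals are a percentile bootstrap: each replicate resamples
persons with replacement, reassigns positional ids, and re-simulates; by
default each replicate also gets fresh simulation randomness so both
cohort-sampling and Monte-Carlo uncertainty propagate (`fresh_sim=False`
restricts to resampling). Intervals are the 2.5/97.5 percentiles of the
replicate estimates with linear interpolation between order statistics —
stated explicitly because percentiles of 100 values are
definition-sensitive. Group differences use a paired-replicate normal
approximation, p = 2Φ(−|d̄|/SE), with SE the standard deviation of the
replicate differences; this is a declared convention, not an attempt to
reproduce any published test. Intervals are reported as computed; the
percentile bootstrap does not guarantee the point estimate is contained.

The six one-way sensitivity analyses scale one of
{obesity→diabetes RR, obesity→hypertension RR, obesity slope coefficient}
by 0.75 or 1.25 (both sexes / both bands together), re-simulate under
identical seeds, and report the obesity-minus-normal difference in any-CKD
risk next to the unscaled reference.

## Problem sizes used by the shipped checks

The test suite runs the deterministic oracle on a 20-person fixture,
distributional checks at n = 100,000 cohort draws and 200,000 slope draws,
the null-effect exchangeability contrast at n = 50,000 per arm, headline
risk tables at n = 10,000 per BMI group, bootstrap behaviour at B ≤ 15 with
n ≤ 2,500, and the sensitivity suite at n = 4,000 per group. The
reproduction script (`scripts/acceptance.py`) uses n = 10,000 per group.
These sizes give Monte-Carlo noise well below the tolerances asserted (a
proportion at n = 10,000 has SE ≤ 0.5 pp).

## Known limitations

- Absolute lifetime-risk levels depend on the invented background
  incidence/mortality tables and cohort marginals; shipped defaults produce
  levels several points above the published figures while reproducing the
  obesity contrasts and orderings (see README). Treat levels as
  illustrative until the tables are replaced with authoritative ones.
- The stage-4/5 tail is sensitive to the persistent-slope policy and the
  unanchored ≥ 60 variance multiplier.
- No treatment effects, smoking, remission, acute kidney injury, eGFR
  measurement error, half-cycle correction, calendar-period effects, or
  ESRD treatment modalities within stage 5.
- Relative risks are applied on the annual probability scale with a cap,
  not on the hazard scale.
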