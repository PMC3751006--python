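# Methods

## Model overview

`prediasim` evaluates one-off population screening for undiagnosed
diabetes and impaired glucose tolerance (IGT), followed by six years of
lifestyle intervention in detected IGT subjects, against a no-screening
control, in a developing-country (Chinese) setting.  The model is a
hybrid of

1. a **decision tree** that assigns each simulated adult a baseline
   status from the screening cascade (2-h plasma glucose test →
   confirmatory OGTT → IGT/diabetes split), including compliance with
   screening and the detection level of IGT; and
2. an **annual-cycle Markov microsimulation** over a 40-year horizon
   with states: normal glucose tolerance; IGT, represented as six
   one-year *tunnel* states (the intervention years) plus a post-tunnel
   IGT state; onset of diabetes; four mutually exclusive complication
   states (CVD, retinopathy, nephropathy, overt neuropathy); and
   absorbing death.

Five arms are simulated on a common latent population: screening with
diet, exercise, or combined (duo) intervention; screening alone; and
control.  Three independent age-specific models are run for initiation
ages 25, 40 and 60, each with its own IGT→diabetes rates and utilities.

## Transition dynamics

Within each cycle, all-cause death from the life table applies first
(`qx` at the subject's current age); disease transitions act
conditionally on survival.  CVD and nephropathy add their
complication-specific annual mortalities on top of `qx`; retinopathy and
neuropathy carry background mortality only, since those complications
are not fatal in this model.  Complications are reachable only from the
onset-of-diabetes state and are absorbing apart from death.

Transition sampling uses inverse-CDF draws over a fixed state ordering
(normal, IGT tunnel, onset, CVD, retinopathy, nephropathy, neuropathy,
death), one uniform deviate per subject-cycle.

**Which rates apply to whom.**  The intervention-arm IGT→diabetes rate
applies only while a subject is *in intervention*: a detected, compliant
IGT subject in a diet/exercise/duo arm, during the six tunnel years.
All other IGT person-years — screen-alone subjects, undetected or
noncompliant subjects, incident IGT arising after baseline, and
post-tunnel years (configurable via `conventions.post_tunnel_rate`) —
progress at the control rate.  A direct consequence is that the
screen-alone arm, which confers no intervention, has IGT progression
identical to control; with common random numbers its extra time before
onset is exactly zero, which matches the near-zero values reported for
screening alone.  Complication incidence and mortality follow the arm's
parameter column for subjects who attended screening, and the control
column for noncompliant subjects.

**Tunnel bookkeeping.**  Tunnel year *k* is only reachable from tunnel
year *k − 1*; fresh IGT always enters tunnel year 1; survivors of year 6
move to the post-tunnel IGT state.  These invariants are property-tested.

## Valuation

Costs (societal perspective, US$ at the fixed rate of 7.6948 CHY/US$)
and QALYs accrue per cycle, discounted at 3% per year and half-cycle
corrected with trapezoidal end-weights (0.5 at cycles 0 and 40).  A
subject dying in cycle *k* is credited *k − ½* life years.  Annual state
costs: diabetes 897, CVD 2078, nephropathy 1089, neuropathy 1324,
retinopathy 888; normal/IGT/death cost nothing.  Intervention costs
(362/year for diet or exercise, 371/year for duo) are charged for tunnel
years actually spent in IGT, at cycles 1–6.  The one-off screening cost
($3, covering the 2-h PG test and any confirmatory OGTT) is charged in
full at cycle 0 to every subject who attends screening.  Remaining
survival years are undiscounted; extra-time outcomes (years gained
before onset, and before any complication) are undiscounted durations,
horizon-censored at 40 years.

## Reporting conventions

Several denominators are under-determined and are exposed in
`conventions`:

* `eligibility` — membership of the "diabetes or IGT subjects"
  denominator for survival/QALY/cost averages.  Default `baseline`
  (IGT or diabetes at entry).  The printed control-arm cost of ≈$20k per
  subject at age 25 is the cost of a 0.478 : 0.522 IGT : diabetes
  baseline mix under the cost table above, whereas an
  incident-diabetes-inclusive denominator is dominated by late-onset
  cases and costs ≈$3k; the baseline definition is therefore the default
  and the one used for the reproduction runs.  `incident` adds subjects
  who develop diabetes within the horizon.
* `cost_population` — `subgroup` (default) or `all` simulated subjects;
  both means are always computed and reported.
* `range_kind` — the parenthesised ranges are subject-level
  2.5th–97.5th percentiles by default (`minmax` optional).
* `post_tunnel_rate` — `control` (default) or `last_intervention` for
  intervention recipients after year 6.

## Randomness and variance reduction

One master seed drives three reproducible streams: latent baseline
states, compliance/detection draws, and the per-subject-per-cycle
uniform matrix.  All arms at an initiation age — and all sensitivity
scenarios — share these streams (common random numbers), so subject *i*
is the same person everywhere and arm/scenario contrasts are paired.
Identical seeds give byte-identical outputs.

Note the scale of residual Monte-Carlo noise: the baseline diabetes/IGT
subgroup is ≈1.2% of the cohort (≈235 of 20,000 subjects), so
subgroup-level cost differences at the default cohort size carry a
between-seed SD of several hundred US$ even with paired sampling.

## Synthetic life table

No machine-readable all-cause mortality schedule accompanies the study,
so the package bundles a synthetic Gompertz–Makeham fixture,
`qx(age) = 1 − exp(−(a + b·c^age))` with a = 5·10⁻⁴, b = 3·10⁻⁵,
c = 1.094, tabulated for ages 20–100 and frozen as a CSV.  These
constants give a horizon-capped (40-year) expected survival of ≈38.6
years for a healthy 25-year-old and residual life expectancies of
≈57/43/25 years at ages 25/40/60 (computed by product-limit summation) —
a deliberately *healthy, contemporary* calibration.  They are documented
constants, not quantities fitted to any reported model output; the
bundled file is regenerated from the formula in a test and compared
bit-exactly.

## Sensitivity analysis

`default_scenario_grid()` enumerates one-at-a-time perturbations:
±20% on screening positivity rates, IGT→diabetes incidence, complication
incidence and mortality, each cost group (screening, intervention,
treatment), all disease utilities, and the discount rate; ×3.0/×0.5 on
the incidence of IGT; and 80%/60% levels for IGT detection and screening
compliance.  Probability or utility products outside [0, 1] are clamped
with a logged warning.  Every scenario reruns the full model under the
baseline seed, so the baseline grid row equals the main run exactly.

## Statistical comparisons

Between-arm comparisons of subject-level QALYs, costs and survival use
the two-sided Wilcoxon rank-sum (Mann–Whitney) test: exact enumeration
for tie-free samples of ≤20 per arm, otherwise the continuity-corrected
normal approximation with midranks (delegated to
`scipy.stats.mannwhitneyu`; an independent full-enumeration oracle backs
it in the tests).  Significance at α = 0.05, unadjusted.

## Numerical choices and degenerate inputs

* Transition rows are validated to sum to 1 (|Δ| ≤ 10⁻¹²) for every
  state × arm × age at simulation start; a negative residual
  stay-probability raises a configuration error naming the state.
* Reported parameter values follow round-half-away-from-zero at the
  table precisions, implemented in decimal arithmetic so values such as
  0.7045 round upward as they do on paper.
* The age-25 IGT→diabetes rates derive from age 40 by division by 2.6
  and 4-d.p. rounding; the age-60 intervention-arm rates equal that
  *rounded* age-25 value × 8 (`derive_igt_dm_rates` mirrors this chained
  rounding; the direct ratio differs in the fourth decimal for the
  exercise arm).  The control and screen-alone age-60 rates do not
  follow the ratio at all; the bundled defaults store every printed
  value verbatim.
* An empty diabetes/IGT subgroup yields NaN summaries with a warning
  rather than an exception; annualising a cumulative probability of 1 is
  rejected as undefined.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis needs —
multinomial screening yields, tunnel entry, competing background
mortality — so the test suite runs with no external data.  It does not
reproduce the source study's national life table, which is not
available in machine-readable form.  That matters: with a realistically healthy mortality schedule,
diabetes/IGT subjects at age 25 retain ≈37 of the 40 horizon years, and
deterministic expected savings of screening-with-diet versus control are
≈ +410/+1220/+1500 US$ per subgroup subject at ages 25/40/60, with
≈0.5–0.7 incremental QALYs and ≈3.7–6.5 extra years before onset for
treated IGT subjects.  The study's published headline outcomes
(savings up to $6808 at age 25, control survival of 29.0 years at 25 and
7.4 at 60) imply several percent annual excess mortality in the
diabetes/IGT cohort, which cannot be produced by the printed transition
parameters (the only disease-specific death rates are 0.0087 from CVD
and 0.0003 from nephropathy) under any plausible all-cause table.
Reproduction runs therefore match the published results in sign and
ordering (interventions dominate screening alone; exercise ≥ duo ≥ diet;
screen-alone extra time ≈ 0) but not in magnitude, and the magnitudes
reported by this package should be read as the model's behaviour under a
transparent, healthy-population mortality fixture.  A related
consequence: with long survivorship, older cohorts' higher progression
rates give the tunnel *more* onsets to avert, so absolute benefits grow
rather than shrink with initiation age.

## Problem sizes

Default runs use the study's cohort size of 20,000 subjects per arm per
age (a full five-arm, three-age run takes a few seconds).  Unit and
property tests use 300–20,000 subjects as each check requires; the
convergence test against the deterministic cohort trace uses 20,000.
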