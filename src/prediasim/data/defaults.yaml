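# Default model configuration: baseline epidemiology, costs (US$),
# utilities and global settings for the screening/intervention
# microsimulation.  Override any subset of keys via a user config file.
strategies:
  diet:
    igt_to_dm_rate_by_age: {25: 0.0290, 40: 0.0754, 60: 0.2320}
    complication_incidence:
      {cvd: 0.062, nephropathy: 0.001, neuropathy: 0.0043, retinopathy: 0.0046}
    complication_mortality: {cvd: 0.0058, nephropathy: 0.0008}
    annual_intervention_cost: 362.0
    has_screening: true
  exercise:
    igt_to_dm_rate_by_age: {25: 0.0273, 40: 0.0710, 60: 0.2184}
    complication_incidence:
      {cvd: 0.062, nephropathy: 0.001, neuropathy: 0.0043, retinopathy: 0.0046}
    complication_mortality: {cvd: 0.0058, nephropathy: 0.0008}
    annual_intervention_cost: 362.0
    has_screening: true
  duo:
    igt_to_dm_rate_by_age: {25: 0.0275, 40: 0.0716, 60: 0.2200}
    complication_incidence:
      {cvd: 0.062, nephropathy: 0.001, neuropathy: 0.0043, retinopathy: 0.0046}
    complication_mortality: {cvd: 0.0058, nephropathy: 0.0008}
    annual_intervention_cost: 371.0
    has_screening: true
  screen_only:
    igt_to_dm_rate_by_age: {25: 0.0400, 40: 0.104, 60: 0.3600}
    complication_incidence:
      {cvd: 0.0675, nephropathy: 0.001, neuropathy: 0.005, retinopathy: 0.0081}
    complication_mortality: {cvd: 0.0087, nephropathy: 0.0003}
    annual_intervention_cost: 0.0
    has_screening: true
  control:
    igt_to_dm_rate_by_age: {25: 0.0644, 40: 0.1670, 60: 0.5778}
    complication_incidence:
      {cvd: 0.0675, nephropathy: 0.001, neuropathy: 0.005, retinopathy: 0.0081}
    complication_mortality: {cvd: 0.0087, nephropathy: 0.0003}
    annual_intervention_cost: 0.0
    has_screening: false

screening:
  neg_rate_2hpg: 0.96
  ogtt_positive_rate: 0.305
  igt_fraction_of_positive: 0.478
  detection_level: 1.0
  compliance: 1.0
  screening_cost: 3.0

shared:
  normal_to_igt: 0.0128
  igt_to_normal: 0.116

costs:
  onset_dm: 897.0
  cvd: 2078.0
  nephropathy: 1089.0
  neuropathy: 1324.0
  retinopathy: 888.0
  screening: 3.0
  diet_or_exercise: 362.0
  duo: 371.0

utilities:
  by_age_and_state:
    25: {normal: 1.0, igt: 0.95, onset_dm: 0.805, cvd: 0.679,
         retinopathy: 0.705, nephropathy: 0.646, neuropathy: 0.667, death: 0.0}
    40: {normal: 1.0, igt: 0.95, onset_dm: 0.800, cvd: 0.674,
         retinopathy: 0.700, nephropathy: 0.641, neuropathy: 0.662, death: 0.0}
    60: {normal: 1.0, igt: 0.95, onset_dm: 0.794, cvd: 0.584,
         retinopathy: 0.610, nephropathy: 0.551, neuropathy: 0.572, death: 0.0}
  age_coefficient: -0.0003
  comorbidity_coefficient: 0.084

settings:
  discount_rate: 0.03
  horizon: 40
  cycle_length: 1
  cohort_size: 20000
  tunnel_length: 6
  fx_rate: 7.6948
  age_ratio: {25: 1.0, 40: 2.6, 60: 8.0}

conventions:
  cost_population: subgroup    # subgroup | all
  eligibility: baseline        # baseline | incident
  post_tunnel_rate: control    # control | last_intervention
  range_kind: percentile       # percentile | minmax
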