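# Default parameterization: 30-year two-arm cohort analysis, 2022 CNY.
# This document is the single source of truth for every model input.
schema_version: 1

cohort:
  age_years: 61
  duration_years: 14.1
  prop_female: 0.359
  prop_smoker: 0.265
  hba1c_pct: 8.3
  sbp_mmHg: 141.5
  dbp_mmHg: 82.4
  tc_mmol: 4.82
  ldl_mmol: 2.75
  hdl_mmol: 1.21
  tg_mmol: 2.42
  bmi: 35.9
  heart_rate_bpm: 72.0
  wbc: 6.8
  egfr: 77.5

arm_intervention:
  name: IDegLira
  hba1c_on_treatment: 7.6
  bmi_on_treatment: 35.83
  sbp_on_treatment: 139.7
  dbp_on_treatment: 83.9
  hypo_nonsevere_rate: 0.06
  hypo_severe_rate: 0.0
  drug_cost_daily: 26.8
  needle_cost_daily: 2.6
  smbg_cost_daily: 8.2
  injections_per_day: 1

arm_comparator:
  name: GLP1RA_plus_basal_insulin
  hba1c_on_treatment: 8.3
  bmi_on_treatment: 35.9
  sbp_on_treatment: 143.2
  dbp_on_treatment: 83.0
  hypo_nonsevere_rate: 0.061
  hypo_severe_rate: 0.0
  drug_cost_daily: [25.8, 8.2]   # GLP-1RA + basal insulin components
  needle_cost_daily: 5.1
  smbg_cost_daily: 8.2
  injections_per_day: 2

switch_rule:
  hba1c_threshold_pct: 8.5
  post_switch_strategy:
    name: basal_bolus
    hba1c_on_treatment: 8.5
    bmi_on_treatment: 35.9
    sbp_on_treatment: 143.2
    dbp_on_treatment: 83.0
    hypo_nonsevere_rate: 5.87
    hypo_severe_rate: 0.352
    drug_cost_daily: 25.3
    needle_cost_daily: 5.1
    smbg_cost_daily: 8.2
    injections_per_day: 4

hba1c_drift_per_year: 0.1

econ:
  horizon_years: 30
  discount_rate_cost: 0.05
  discount_rate_qaly: 0.05
  wtp_threshold: 85698
  days_per_year: 365.25
  discount_from_cycle_one: false
  half_cycle_correction: false

background_cost:
  mean: 3349
  se: null

hypo_costs:
  nonsevere: {mean: 880, se: null}
  severe: {mean: 13790, se: null}

costs:
  bdr: {event_cost: 15757, state_cost: 907}
  pdr: {event_cost: 15757, state_cost: 907}
  me: {event_cost: 16444, state_cost: 2163}
  pdr_me: {event_cost: 32201, state_cost: 3070}
  svl: {event_cost: 14950, state_cost: 11538}
  neuropathy: {event_cost: 18768, state_cost: 7201}
  pvd: {event_cost: 28220, state_cost: 10968}
  amputation: {event_cost: 22625, state_cost: 18035}
  amputation_history: {event_cost: 0, state_cost: 18035}
  microalbuminuria: {event_cost: 0, state_cost: 0}
  macroalbuminuria: {event_cost: 14911, state_cost: 5668}
  esrd: {event_cost: 158396, state_cost: 127391}
  ihd: {event_cost: 48446, state_cost: 8649}
  ihd_history: {event_cost: 0, state_cost: 8649}
  mi: {event_cost: 80620, state_cost: 25485}
  mi_history: {event_cost: 0, state_cost: 25485}
  mi_subsequent: {event_cost: 80620, state_cost: 25485}
  mi_subsequent_history: {event_cost: 0, state_cost: 25485}
  stroke: {event_cost: 31923, state_cost: 15793}
  stroke_history: {event_cost: 0, state_cost: 15793}
  stroke_subsequent: {event_cost: 31923, state_cost: 15793}
  stroke_subsequent_history: {event_cost: 0, state_cost: 15793}
  hf: {event_cost: 38623, state_cost: 20489}
  hf_history: {event_cost: 0, state_cost: 20489}

utilities:
  baseline: {mean: 0.936, se: 0.120}
  bmi_anchor: 35.9
  demographic:
    age_per_10_years: {mean: -0.024, se: 0.002}
    female: {mean: -0.012, se: 0.001}
    duration_per_10_years: {mean: -0.016, se: 0.002}
    bmi_per_unit: {mean: -0.006, se: 0.001}
  states:
    bdr: {mean: -0.023, se: 0.002}
    pdr: {mean: -0.023, se: 0.002}
    me: {mean: -0.019, se: 0.002}
    pdr_me: {mean: -0.023, se: 0.002}
    svl: {mean: -0.049, se: 0.005}
    neuropathy: {mean: -0.026, se: 0.003}
    pvd: {mean: -0.032, se: 0.003}
    amputation: {mean: -0.139, se: 0.014}
    amputation_history: {mean: -0.139, se: 0.014}
    microalbuminuria: {mean: 0.0, se: null}
    macroalbuminuria: {mean: -0.030, se: 0.003}
    esrd: {mean: -0.092, se: 0.009}
    ihd: {mean: -0.068, se: 0.007}
    ihd_history: {mean: -0.068, se: 0.007}
    mi: {mean: -0.050, se: 0.005}
    mi_history: {mean: -0.050, se: 0.005}
    mi_subsequent: {mean: -0.012, se: 0.001}
    mi_subsequent_history: {mean: -0.012, se: 0.001}
    stroke: {mean: -0.106, se: 0.011}
    stroke_history: {mean: -0.106, se: 0.011}
    stroke_subsequent: {mean: -0.040, se: 0.004}
    stroke_subsequent_history: {mean: -0.040, se: 0.004}
    hf: {mean: -0.186, se: 0.019}
    hf_history: {mean: -0.186, se: 0.019}
  events:
    hypo_nonsevere: {mean: -0.014, se: 0.0014}
    hypo_severe: {mean: -0.047, se: 0.0047}
  injections_per_day:
    # 3 and 4 injections/day extrapolate the printed 1- and 2-injection rows
    1: {mean: -0.00805, se: 0.0008}
    2: {mean: -0.0101, se: 0.0010}
    3: {mean: -0.01215, se: 0.0012}
    4: {mean: -0.0142, se: 0.0014}

submodels:
  - id: eye
    states: [eye_none, bdr, pdr, me, pdr_me, svl]
    transitions:
      - [eye_none, bdr, eye_bdr]
      - [bdr, pdr, eye_pdr]
      - [bdr, me, eye_me]
      - [pdr, pdr_me, eye_pdrme]
      - [me, pdr_me, eye_pdrme]
      - [pdr, svl, eye_svl]
      - [me, svl, eye_svl]
      - [pdr_me, svl, eye_svl]
  - id: lower_extremity
    states: [lex_none, neuropathy, pvd, amputation, amputation_history]
    transitions:
      - [lex_none, neuropathy, lex_neuropathy]
      - [lex_none, pvd, lex_pvd]
      - [neuropathy, amputation, lex_amputation]
      - [pvd, amputation, lex_amputation]
      - [amputation, amputation_history, always]
  - id: renal
    states: [renal_none, microalbuminuria, macroalbuminuria, esrd]
    transitions:
      - [renal_none, microalbuminuria, renal_micro]
      - [microalbuminuria, macroalbuminuria, renal_macro]
      - [macroalbuminuria, esrd, renal_esrd]
  - id: ihd
    states: [ihd_none, ihd, ihd_history]
    transitions:
      - [ihd_none, ihd, ihd_first]
      - [ihd, ihd_history, always]
  - id: mi
    states: [mi_none, mi, mi_history, mi_subsequent, mi_subsequent_history]
    transitions:
      - [mi_none, mi, mi_first]
      - [mi, mi_history, always]
      - [mi_history, mi_subsequent, mi_subsequent_eq]
      - [mi_subsequent, mi_subsequent_history, always]
  - id: stroke
    states: [stroke_none, stroke, stroke_history, stroke_subsequent, stroke_subsequent_history]
    transitions:
      - [stroke_none, stroke, stroke_first]
      - [stroke, stroke_history, always]
      - [stroke_history, stroke_subsequent, stroke_subsequent_eq]
      - [stroke_subsequent, stroke_subsequent_history, always]
  - id: heart_failure
    states: [hf_none, hf, hf_history]
    transitions:
      - [hf_none, hf, hf_first]
      - [hf, hf_history, always]

mortality:
  all_cause_equation: death_all
  cv_equation: death_cv

history_covariates:
  prior_mi: [mi, mi_history, mi_subsequent, mi_subsequent_history]
  prior_stroke: [stroke, stroke_history, stroke_subsequent, stroke_subsequent_history]
  prior_ihd: [ihd, ihd_history]
  prior_hf: [hf, hf_history]
  prior_amputation: [amputation, amputation_history]
  prior_esrd: [esrd]

cost_categories:
  eye: [bdr, pdr, me, pdr_me, svl]
  lower_extremity: [neuropathy, pvd, amputation, amputation_history]
  kidney: [microalbuminuria, macroalbuminuria, esrd]
  ihd: [ihd, ihd_history]
  mi: [mi, mi_history, mi_subsequent, mi_subsequent_history]
  stroke: [stroke, stroke_history, stroke_subsequent, stroke_subsequent_history]
  heart_failure: [hf, hf_history]

risk_coefficients: builtin:risk_coefficients.csv

treatment_effects:
  # means are the between-arm differences implied by the on-treatment
  # values above; CIs parameterize the PSA normal draws (sd = width/3.92)
  hba1c_diff: {mean: -0.7, low: -0.8, high: -0.4}
  bmi_diff: {mean: -0.07, low: null, high: null}
  sbp_diff: {mean: -3.5, low: -5.7, high: -1.3}
  dbp_diff: {mean: 0.9, low: -0.4, high: 2.2}
  hypo_rr: {mean: 0.98, low: 0.63, high: 1.54}
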