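parameters:
  accept_fcbt:
    family: beta
    base: 0.633
    low: 0.506
    high: 0.76
  rr_accept_icbt:
    family: triangular
    base: 1.19
    low: 0.952
    high: 1.428
  adhere_fcbt:
    family: beta
    base: 0.775
    low: 0.62
    high: 0.93
  rr_adhere_icbt:
    family: triangular
    base: 0.99
    low: 0.84
    high: 1.0
  recovery_none:
    family: beta
    base: 0.25
    low: 0.2
    high: 0.3
  recovery_licbt:
    family: beta
    base: 0.639
    low: 0.511
    high: 0.767
  rr_recovery_icbt:
    family: triangular
    base: 1.0
    low: 0.95
    high: 1.05
  deterioration_none:
    family: beta
    base: 0.174
    low: 0.139
    high: 0.209
  deterioration_licbt:
    family: beta
    base: 0.053
    low: 0.042
    high: 0.064
  rr_deterioration_icbt:
    family: triangular
    base: 1.0
    low: 0.95
    high: 1.05
  p_well_mild:
    family: beta
    base: 0.0044
    low: 0.0035
    high: 0.0053
  p_well_mod:
    family: beta
    base: 0.0053
    low: 0.0042
    high: 0.0064
  p_well_sev:
    family: beta
    base: 0.0166
    low: 0.0133
    high: 0.0199
  p_mild_well:
    family: beta
    base: 0.0239
    low: 0.0191
    high: 0.0287
  p_mild_mod:
    family: beta
    base: 0.0073
    low: 0.0058
    high: 0.0088
  p_mild_sev:
    family: beta
    base: 0.0067
    low: 0.0054
    high: 0.008
  p_mod_well:
    family: beta
    base: 0.0448
    low: 0.0358
    high: 0.0538
  p_mod_mild:
    family: beta
    base: 0.0801
    low: 0.0641
    high: 0.0961
  p_mod_sev:
    family: beta
    base: 0.0275
    low: 0.022
    high: 0.033
  p_sev_well:
    family: beta
    base: 0.0387
    low: 0.031
    high: 0.0464
  p_sev_mild:
    family: beta
    base: 0.0314
    low: 0.0251
    high: 0.0377
  p_sev_mod:
    family: beta
    base: 0.0391
    low: 0.0313
    high: 0.0469
  p_hosp_severe:
    family: beta
    base: 0.0114
    low: 0.0091
    high: 0.0137
  mortality_monthly:
    family: beta
    base: 2.5e-05
    low: 2.0e-05
    high: 3.0e-05
  rr_mortality_anxiety:
    family: triangular
    base: 1.66
    low: 1.56
    high: 1.77
  age_years:
    family: triangular
    base: 21
    low: 19
    high: 23
  utility_age:
    family: fixed
    base: 0.92
    low: 0.92
    high: 0.92
  utility_well:
    family: triangular
    base: 0.72
    low: 0.69
    high: 0.75
  utility_mild:
    family: triangular
    base: 0.64
    low: 0.62
    high: 0.66
  utility_mod:
    family: triangular
    base: 0.6
    low: 0.58
    high: 0.62
  utility_sev:
    family: triangular
    base: 0.53
    low: 0.5
    high: 0.56
  wage_psych:
    family: triangular
    base: 52
    low: 42
    high: 62
  li_sessions:
    family: triangular
    base: 8
    low: 5
    high: 10
  li_session_hours:
    family: fixed
    base: 0.5
    low: 0.5
    high: 0.5
  hi_sessions:
    family: triangular
    base: 14
    low: 12
    high: 15
  hi_session_hours:
    family: fixed
    base: 1.0
    low: 1.0
    high: 1.0
  platform_cost_icbt:
    family: triangular
    base: 19
    low: 15
    high: 23
  time_fraction_icbt:
    family: triangular
    base: 0.22
    low: 0.17
    high: 0.26
  outpatient_monthly:
    family: triangular
    base: 220
    low: 185
    high: 348
  hosp_cost_episode:
    family: triangular
    base: 1278
    low: 1022
    high: 1534
  labor_participation:
    family: beta
    base: 0.364
    low: 0.353
    high: 0.387
  unemployment:
    family: beta
    base: 0.13
    low: 0.114
    high: 0.144
  student_wage:
    family: triangular
    base: 10
    low: 8
    high: 12
  hours_per_month:
    family: triangular
    base: 56
    low: 40
    high: 72
  discount_annual:
    family: fixed
    base: 0.03
    low: 0.03
    high: 0.03
  horizon_cycles:
    family: fixed
    base: 60
    low: 60
    high: 60
  wtp:
    family: fixed
    base: 46070
    low: 46070
    high: 46070
structural:
  phase_cycles: 3
  deterioration_split_rule: proportional
  outpatient_states:
  - moderate
  - severe
  escalation_enabled: true
  escalation_recipients: all_not_well
  course_cost_nonadherent: full
  half_cycle_correction: false
  mortality_rr_states:
  - mild
  - moderate
  - severe
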