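cycle_length: 0.5
discount_rate_annual: 0.05
horizon: 35.0
origin_mix:
  index: 0.52
  surv: 0.48
params:
  background_mortality_rate: 0.0088
  cost_advanced_care_cycle: 2000.0
  cost_advanced_care_event: 80000.0
  cost_emr: 5000.0
  cost_endoscopy: 1500.0
  cost_rfa: 7000.0
  cost_rfa_complication: 6000.0
  disutility_emr: 0.05
  disutility_rfa: 0.05
  disutility_rfa_complication: 0.1
  eac_advanced_mortality_rate: 0.35
  frac_eac_advanced: 0.15
  frac_eac_given_progression_index: 0.14285714285714285
  frac_eac_given_progression_nd: 0.4
  frac_eac_given_progression_surv: 0.35714285714285715
  hgd_detection_prob_per_cycle: 0.85
  hgd_eac_rate: 0.1
  lgd_progression_rate_index: 0.015216
  lgd_progression_rate_surv: 0.045517
  lgd_reversion_rate: 0.418778
  nd_lgd_recurrence_rate: 0.053483
  nd_progression_rate: 0.006457
  post_emr_recurrence_rate: 0.03
  post_rfa_progression_rate: 0.003
  post_rfa_recurrence_rate: 0.02
  rfa_complication_prob: 0.05
  t1a_detection_prob_per_cycle: 0.75
  t1a_mortality_rate: 0.02
  t1a_progression_rate: 0.3
  utility_eac_advanced: 0.5
  utility_eac_t1a: 0.85
  utility_hgd: 0.9
  utility_lgd: 0.93
  utility_ndbe: 0.97
  utility_post_emr: 0.9
  utility_post_rfa: 0.95
provenance:
  background_mortality_rate: placeholder
  cost_advanced_care_cycle: placeholder
  cost_advanced_care_event: placeholder
  cost_emr: placeholder
  cost_endoscopy: placeholder
  cost_rfa: placeholder
  cost_rfa_complication: placeholder
  disutility_emr: placeholder
  disutility_rfa: placeholder
  disutility_rfa_complication: placeholder
  eac_advanced_mortality_rate: placeholder
  frac_eac_advanced: placeholder
  frac_eac_given_progression_index: study-observed
  frac_eac_given_progression_nd: study-observed
  frac_eac_given_progression_surv: study-observed
  hgd_detection_prob_per_cycle: placeholder
  hgd_eac_rate: placeholder
  lgd_progression_rate_index: study-calibrated
  lgd_progression_rate_surv: study-calibrated
  lgd_reversion_rate: study-calibrated
  nd_lgd_recurrence_rate: study-calibrated
  nd_progression_rate: study-observed
  post_emr_recurrence_rate: placeholder
  post_rfa_progression_rate: placeholder
  post_rfa_recurrence_rate: placeholder
  rfa_complication_prob: placeholder
  t1a_detection_prob_per_cycle: placeholder
  t1a_mortality_rate: placeholder
  t1a_progression_rate: placeholder
  utility_eac_advanced: placeholder
  utility_eac_t1a: placeholder
  utility_hgd: placeholder
  utility_lgd: placeholder
  utility_ndbe: placeholder
  utility_post_emr: placeholder
  utility_post_rfa: placeholder
wtp: 50000.0
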