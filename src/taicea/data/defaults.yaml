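# Base-case parameter set for the TAI vs SBC cost-effectiveness model
# (Japanese setting). All monetary values are yen; all rates are per
# 6-month model cycle unless noted otherwise.

settings:
  cycle_length_years: 0.5
  annual_discount_rate: 0.02
  age_cutoff: 110.0          # "lifetime" horizon realized as simulation to this age
  start_age: 51.46
  male_fraction: 0.783
  perspective: payer         # payer | societal_absenteeism | societal_full
  tai_procedure_fee_per_month: 18000   # one of 8100, 13050, 18000
  half_cycle_correction: false
  smr: 1.0                   # excess-mortality multiplier on the life table
  seed: 0

clinical:
  responder_fraction: 0.60
  nonresponder_withdrawal_per_cycle: 0.60
  all_nonresponders_withdraw_after_first_cycle: false
  nbds_baseline: 16.74
  nbds_delta_responder: -6.0
  nbds_delta_nonresponder: 1.0
  uti_rate_sbc_per_cycle: 0.512
  uti_rate_tai_per_cycle: 0.195
  hosp_decubitus_sbc: 0.31
  hosp_decubitus_tai: 0.14
  hosp_other_sbc: 1.73
  hosp_other_tai: 0.77
  hospitalization_recall_years: 8.5
  nursing_rate_sbc: 0.318
  nursing_rate_tai: 0.1941
  nursing_visits_per_week: 2
  stoma_rate_per_cycle: 0.00033
  laparoscopic_fraction: 0.575
  uti_split_hospitalized: 0.086
  uti_split_outpatient: 0.811
  uti_split_untreated: 0.103
  stoma_events_at_sbc_rates: true   # stoma state keeps SBC-level UTI/hosp/nursing

utility:
  u_responder: 0.533
  u_nonresponder: 0.470
  u_sbc: 0.479
  u_stoma: 0.564
  du_uti_per_event: 0.060
  du_hosp_per_event: 0.010

cost:
  device_cost_per_year: 280945
  peristeen_system_cost_per_set: 12095
  peristeen_system_sets_per_year: 2
  peristeen_accessory_cost_per_year: 256755
  sbc_cost_per_month: 4151
  stoma_fee_laparoscopic: 139200
  stoma_fee_open: 79800
  stoma_hosp_laparoscopic: 236311
  stoma_hosp_open: 242686
  stoma_mgmt_month_y1: 4131
  stoma_mgmt_month_after: 1621
  uti_cost_hospitalized: 163113
  uti_cost_outpatient: 14126
  uti_cost_untreated: 10293
  nursing_cost_per_visit: 5800
  nursing_premium_per_week: 5200
  hosp_cost_decubitus: 1512630
  hosp_cost_other: 630960

productivity:
  employment_rate: 0.488
  absenteeism_minor: 0.0
  absenteeism_moderate: 0.0221
  absenteeism_severe: 0.0701
  presenteeism_minor: 0.17
  presenteeism_moderate: 0.3636
  presenteeism_severe: 0.3971
  wage_per_month_50_54: 364163
  wage_per_month_55_59: 350789
  wage_per_month_60_64: 262659
  wage_per_month_65_69: 244283
  wage_per_month_70_plus: 248227
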