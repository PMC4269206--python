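# STEMI subgroup (low-dose ASA), 2009 EUR.
cohort:
  label: stemi
  start_age: 62
  male_fraction: 0.72
  max_age: 110
  cohort_scale: 1.0
arm_ticagrelor:
  arm_label: ticagrelor
  p_mi: 0.026
  p_stroke: 0.008
  p_death: 0.032
  u_no_event: 0.891
  u_mi: 0.879
  u_stroke: 0.763
  u_death: 0.228
arm_clopidogrel:
  arm_label: clopidogrel
  p_mi: 0.038
  p_stroke: 0.007
  p_death: 0.046
  u_no_event: 0.899
  u_mi: 0.855
  u_stroke: 0.833
  u_death: 0.281
longterm:
  q_mi: 0.016
  q_stroke: 0.003
  q_cv_fatal: 0.015
  u_no_event_by_age_band:
    "60-69": 0.895
    "70-79": 0.856
    "80+": 0.789
  du_stroke_y1: 0.097
  du_stroke_y2plus: 0.097
  du_mi_y1: 0.028
  du_mi_y2plus: 0.028
hazard_ratios:
  hr_no_event: 1.0
  hr_mi_y1: 1.6
  hr_mi_y2plus: 1.4
  hr_stroke_y1: 3.23
  hr_stroke_y2plus: 1.5
costs:
  c_mi_y1: 10980.0         # 9558 with the 4226 acute component replaced by 5648
  c_stroke_y1: 14925.0
  c_mi_y2plus: 3421.0
  c_stroke_y2plus: 4336.0
  c_death: 8650.0
  c_no_event_annual: 974.0
  indirect_mi_y1: 2744.0
  indirect_stroke_y1: 4417.0
  indirect_stroke_y2plus: 4336.0
  dtc_ticagrelor: 2.90
  dtc_clopidogrel: 0.72
  drug_days: 365.0
  drug_death_fraction: 0.5
discount:
  rate_costs: 0.03
  rate_effects: 0.03
life_table_ref: german_2009
seed: 2013
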