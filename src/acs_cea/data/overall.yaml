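# Overall ACS patient population (low-dose ASA), 2009 EUR.
cohort:
  label: overall
  start_age: 62
  male_fraction: 0.72
  max_age: 110
  cohort_scale: 1.0
arm_ticagrelor:
  arm_label: ticagrelor
  p_mi: 0.041
  p_stroke: 0.008
  p_death: 0.036
  u_no_event: 0.875
  u_mi: 0.817
  u_stroke: 0.748
  u_death: 0.259
arm_clopidogrel:
  arm_label: clopidogrel
  p_mi: 0.049
  p_stroke: 0.008
  p_death: 0.050
  u_no_event: 0.878
  u_mi: 0.801
  u_stroke: 0.720
  u_death: 0.249
longterm:
  q_mi: 0.021
  q_stroke: 0.004
  q_cv_fatal: 0.019
  u_no_event_by_age_band:
    "60-69": 0.877
    "70-79": 0.838
    "80+": 0.773
  du_stroke_y1: 0.143
  du_stroke_y2plus: 0.143
  du_mi_y1: 0.068
  du_mi_y2plus: 0.068
hazard_ratios:
  hr_no_event: 1.0
  hr_mi_y1: 1.6
  hr_mi_y2plus: 1.4
  hr_stroke_y1: 3.23
  hr_stroke_y2plus: 1.5
costs:
  c_mi_y1: 9558.0          # 4226 acute + 2601 further hosp + 1757 rehab + 975 visits (printed total)
  c_stroke_y1: 14925.0
  c_mi_y2plus: 3421.0
  c_stroke_y2plus: 4336.0
  c_death: 8650.0
  c_no_event_annual: 974.0  # scenario only: GP/cardiologist follow-up assumption
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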