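# Dakar scenario preset (main analysis: whole-city baseline, 13% control).
# Cohort counts, control rates, unit costs, utilities, thresholds, and program
# cost are the published city values; risk machinery and life table are
# illustrative (see ulaanbaatar.yaml header).
cohort:
  city_label: Dakar
  n_patients: 5236
  male_fraction: 0.22
  mean_age: 58
  risk_distribution: {low: 0.30, medium: 0.45, high: 0.25}
  control_rate_baseline: 0.13
  control_rate_end: 0.19
  implementation_years: 1.0
  hypertension_threshold_label: "140/90 mmHg"
risk:
  ten_year_cvd_risk:
    male: {low: 0.05, medium: 0.15, high: 0.30}
    female: {low: 0.03, medium: 0.10, high: 0.22}
  hazard_ratio_controlled:
    male: {low: 0.80, medium: 0.70, high: 0.60}
    female: {low: 0.80, medium: 0.70, high: 0.60}
  stroke_fraction: 0.30
  mortality_multiplier_uncontrolled: 3.0
  mortality_mode: calibrated
economics:
  annual_htn_cost: 139
  chd_event_cost: 1111
  stroke_event_cost: 4280
  productivity_loss_annual: 112
  program_cost_total: 428927
  program_cost_accrual: once
  ppp_factor: 1.37
  discount_rate: 0.03
  age_band_utilities: {"50-59": 0.84, "60-69": 0.82, "70-79": 0.78, "80-100": 0.74}
  event_disutility: {chd: 0.018, stroke: 0.048}
  icer_threshold_low: 73
  icer_threshold_high: 1166
  gdp_per_capita: 1458
life_table_path: life_table_synthetic_senegal.csv
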