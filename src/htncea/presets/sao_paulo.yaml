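# São Paulo (Itaquera district) scenario preset.
# Cohort counts, control rates, unit costs, utilities, thresholds, and program
# cost are the published city values; risk machinery and life table are
# illustrative (see ulaanbaatar.yaml header).  São Paulo is the cost reference
# city, so its PPP factor is 1.
cohort:
  city_label: "São Paulo"
  n_patients: 5844
  male_fraction: 0.27
  mean_age: 62
  risk_distribution: {low: 0.25, medium: 0.40, high: 0.35}
  control_rate_baseline: 0.12
  control_rate_end: 0.31
  implementation_years: 1.25
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
  annual_htn_cost: 191
  chd_event_cost: 1522
  stroke_event_cost: 5864
  productivity_loss_annual: 153
  program_cost_total: 591229
  program_cost_accrual: once
  ppp_factor: 1.0
  discount_rate: 0.05
  age_band_utilities: {"50-59": 0.84, "60-69": 0.82, "70-79": 0.78, "80-100": 0.74}
  event_disutility: {chd: 0.018, stroke: 0.048}
  icer_threshold_low: 3210
  icer_threshold_high: 10122
  gdp_per_capita: 9151
life_table_path: life_table_synthetic_brazil.csv
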