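# Ulaanbaatar scenario preset.
# Cohort counts, control rates, unit costs, utilities, thresholds, and program
# cost are the published city values.  The 10-year risks, hazard ratios, and
# risk-category distribution are illustrative Framingham-style defaults (the
# original supplementary values are not public), and the life table is a
# synthetic Gompertz stand-in for national mortality data.
cohort:
  city_label: Ulaanbaatar
  n_patients: 10075
  male_fraction: 0.37
  mean_age: 61
  risk_distribution: {low: 0.55, medium: 0.35, high: 0.10}
  control_rate_baseline: 0.03
  control_rate_end: 0.19
  implementation_years: 1.75
  hypertension_threshold_label: "130/80 mmHg"
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
  annual_htn_cost: 34
  chd_event_cost: 273
  stroke_event_cost: 1053
  productivity_loss_annual: 27
  program_cost_total: 663771
  program_cost_accrual: once
  ppp_factor: 5.57
  discount_rate: 0.03
  age_band_utilities: {"50-59": 0.84, "60-69": 0.82, "70-79": 0.78, "80-100": 0.74}
  event_disutility: {chd: 0.018, stroke: 0.048}
  icer_threshold_low: 1624
  icer_threshold_high: 4849
  gdp_per_capita: 4135
life_table_path: life_table_synthetic_mongolia.csv
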