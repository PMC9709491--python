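# Default model inputs.
#
# Each entry is either a bare number or a mapping with:
#   value:      point estimate
#   ci95:       [lower, upper] 95% interval (bootstrap percentiles where estimated on
#               trial data); drives the probabilistic-sensitivity-analysis distribution
#   range:      [low, high] deterministic sensitivity range (uniform in PSA)
#   provenance: one of paper_table_III | paper_table_I | paper_methods | placeholder_literature
#
# 18-month outcome probabilities under each arm (crude bootstrap proportions).
p_late_placebo: {value: 0.2149, ci95: [0.1286, 0.3143], provenance: paper_table_III}
p_quiescent_placebo: {value: 0.2209, ci95: [0.1286, 0.3429], provenance: paper_table_III}
p_late_ada: {value: 0.1800, ci95: [0.1000, 0.2857], provenance: paper_table_III}
p_quiescent_ada: {value: 0.3696, ci95: [0.2571, 0.4857], provenance: paper_table_III}

# Linear regression predicting QALYs between 6 and 18 months (all participants).
qaly_gain_quiescence: {value: 0.0395, ci95: [0.0079, 0.0704], provenance: paper_table_III}
qaly_reg_baseline_utility_coef: {value: 0.5410, ci95: [0.4015, 0.6887], provenance: paper_table_III}
qaly_reg_constant: {value: 0.3847, ci95: [0.2581, 0.5161], provenance: paper_table_III}

# Linear regression predicting 18-month change in flexion deformity (placebo group).
fd_change_constant: {value: 0.8631, ci95: [-2.0005, 4.1074], provenance: paper_table_III}
fd_change_ectopic_coef: {value: 8.5189, ci95: [2.1683, 15.3596], provenance: paper_table_III}
fd_change_rmse: {value: 12.6079, provenance: paper_table_III}

# Model schedule and structural assumptions.
cycle_length: {value: 0.5, provenance: paper_table_I}
horizon: {value: 55.0, provenance: paper_table_I}
trial_period: {value: 1.5, provenance: paper_table_I}
discount_rate: {value: 0.035, provenance: paper_table_I}
late_stage_threshold: {value: 30.0, provenance: paper_table_I}
quiescence_duration: {value: 3.0, range: [1.5, 5.0], provenance: paper_table_I}

# Costs (2018-19 GBP).
cost_per_dose: {value: 475.0, provenance: paper_methods}
doses_per_course: {value: 4, provenance: paper_methods}
# Per-patient non-intervention NHS cost over the 18-month trial period (applied to every
# strategy); trial resource use other than the intervention was negligible.
trial_background_cost: {value: 307.0, provenance: placeholder_literature}

# Value-of-information population scaling.
uk_prevalent_cases: {value: 2584411, provenance: paper_methods}

# Willingness-to-pay grid, GBP per QALY.
wtp_grid:
  value: [0, 1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000, 9000, 10000,
          11000, 12000, 13000, 14000, 15000, 16000, 17000, 18000, 19000, 20000,
          21000, 22000, 23000, 24000, 25000, 26000, 27000, 28000, 29000, 30000,
          32000, 34000, 36000, 38000, 40000, 42000, 44000, 46000, 48000, 50000]
  provenance: paper_methods
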