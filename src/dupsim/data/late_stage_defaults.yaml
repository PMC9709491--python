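# PLACEHOLDER late-stage and mortality inputs.
#
# None of these values are printed in the main text of the source study (they derive from
# supplementary material and cited literature: late-stage Markov transition probabilities
# and surgical unit costs from a published late-stage Dupuytren's model, and a data-linkage
# mortality study).  Every value below is therefore a documented assumption
# (provenance: placeholder_literature), chosen once to be clinically plausible and to
# reproduce the base-case standard-care surgical workload and life expectancy; they are
# ordinary config inputs and can be overridden by any user configuration file.
#
# Probabilities are per 6-month cycle unless stated otherwise.

late_stage:
  # Probability that an eligible patient (untreated or relapsed late-stage disease)
  # elects surgery in a given cycle.
  p_elect_surgery: {value: 0.10, ci95: [0.06, 0.15], provenance: placeholder_literature}
  # Probability that a PNF initially succeeds (post-operative flexion deformity <= 5 deg).
  p_pnf_success: {value: 0.70, ci95: [0.55, 0.83], provenance: placeholder_literature}
  # Per-cycle relapse probability after an initially successful procedure.
  p_relapse_pnf: {value: 0.035, ci95: [0.020, 0.055], provenance: placeholder_literature}
  p_relapse_fasciectomy: {value: 0.010, ci95: [0.005, 0.018], provenance: placeholder_literature}
  p_relapse_dermofasciectomy: {value: 0.006, ci95: [0.003, 0.011], provenance: placeholder_literature}
  # Unit costs (2018-19 GBP), procedure only.
  cost_pnf: {value: 800.0, ci95: [620.0, 980.0], provenance: placeholder_literature}
  cost_limited_fasciectomy: {value: 3100.0, ci95: [2500.0, 3700.0], provenance: placeholder_literature}
  cost_dermofasciectomy: {value: 4400.0, ci95: [3500.0, 5300.0], provenance: placeholder_literature}
  # Outpatient + physiotherapy visits accompanying any procedure.
  cost_surgery_followup: {value: 200.0, ci95: [120.0, 280.0], provenance: placeholder_literature}
  # Annualized EQ-5D utility decrements relative to progressive early-stage disease.
  utility_decrement_late_untreated: {value: 0.08, ci95: [0.04, 0.12], provenance: placeholder_literature}
  utility_decrement_post_pnf_success: {value: 0.02, ci95: [0.01, 0.03], provenance: placeholder_literature}
  utility_decrement_post_pnf_failed: {value: 0.07, ci95: [0.035, 0.105], provenance: placeholder_literature}
  utility_decrement_post_fasciectomy: {value: 0.03, ci95: [0.015, 0.045], provenance: placeholder_literature}
  utility_decrement_post_dermofasciectomy: {value: 0.03, ci95: [0.015, 0.045], provenance: placeholder_literature}

mortality:
  # Synthetic Gompertz life table approximating UK adult all-cause mortality:
  # annual hazard h(age) = gompertz_rate * exp(gompertz_shape * age), unisex.
  # Overridable by a user-supplied life-table CSV (age, sex, annual hazard).
  gompertz_rate: {value: 1.253e-05, provenance: placeholder_literature}
  gompertz_shape: {value: 0.1015, provenance: placeholder_literature}
  # Excess all-cause mortality of patients with Dupuytren's disease vs the general
  # population (hazard ratio, independent of disease stage and treatment).
  dd_hazard_ratio: {value: 1.27, ci95: [1.10, 1.45], provenance: placeholder_literature}
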