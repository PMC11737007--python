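# Diet-related cancer PAF analysis, Italy: national food-consumption
# survey summaries (2005-06) against 2020 registry counts, assuming a
# ~15-year exposure-to-outcome lag.
schema_version: 1
name: italy2020
exposure_year: 2005
outcome_year: 2020

intake_summaries: intake_summaries.csv
cancer_counts: cancer_counts.csv

simulation:
  n_sims: 10000
  seed: 20200
  ci_level: 0.95

discretization:
  n_consumer_categories: 10
  cap_quantile: null   # null -> 1 - 0.1/K (0.99 for K = 10)

aggregates:
  diet_related: diet_related
  all_cancers: all_cancers

# registry sources do not report these subtypes; derived from parent
# sites by fixed fractions (cardia counts are taken directly from the
# counts table instead)
subtype_rules:
  - parent: oral_pharyngeal
    subtype: nasopharynx
    fraction: {male: 0.087, female: 0.069}
  - parent: esophagus
    subtype: esophagus_ac
    fraction: 0.33
  - parent: esophagus
    subtype: esophagus_scc
    fraction: 0.67

pairs:
  - factor: processed_meat
    cancer: colorectum
    sexes: [male, female]
    rr: {value: 1.16, ci: [1.10, 1.28], increment: 50, form: continuous}
    counterfactual: {kind: zero_intake}
  - factor: red_meat
    cancer: colorectum
    sexes: [male, female]
    rr: {value: 1.12, ci: [1.00, 1.25], increment: 100, form: continuous}
    counterfactual: {kind: at_most, threshold: 50}
  - factor: dairy
    cancer: colorectum
    sexes: [male, female]
    rr: {value: 0.87, ci: [0.83, 0.90], increment: 400, form: continuous}
    counterfactual: {kind: at_least, threshold: 300}
  - factor: fiber
    cancer: colorectum
    sexes: [male, female]
    rr: {value: 0.93, ci: [0.87, 1.00], increment: 10, form: continuous}
    counterfactual: {kind: at_least, threshold: 30}
  - factor: vegetables
    cancer: mouth_pharynx_larynx
    sexes: [male, female]
    rr: {value: 0.96, ci: [0.92, 1.01], increment: 25, form: continuous}
    counterfactual: {kind: at_least, threshold: 240}
  - factor: vegetables
    cancer: nasopharynx
    sexes: [male, female]
    rr: {value: 0.74, ci: [0.60, 0.92], increment: 100, form: continuous}
    counterfactual: {kind: at_least, threshold: 240}
  - factor: vegetables
    cancer: esophagus_ac
    sexes: [male, female]
    rr: {value: 0.89, ci: [0.80, 0.99], increment: 100, form: continuous}
    counterfactual: {kind: at_least, threshold: 240}
  - factor: vegetables
    cancer: esophagus_scc
    sexes: [male, female]
    rr: {value: 0.91, ci: [0.81, 1.03], increment: 100, form: continuous}
    counterfactual: {kind: at_least, threshold: 240}
  - factor: vegetables
    cancer: colorectum
    sexes: [male, female]
    rr: {value: 0.98, ci: [0.96, 0.99], increment: 100, form: continuous}
    counterfactual: {kind: at_least, threshold: 240}
  - factor: vegetables
    cancer: lung
    sexes: [male, female]
    rr: {value: 0.94, ci: [0.89, 0.98], increment: 100, form: continuous}
    counterfactual: {kind: at_least, threshold: 240}
  - factor: fruit
    cancer: esophagus_scc
    sexes: [male, female]
    rr: {value: 0.84, ci: [0.75, 0.94], increment: 100, form: continuous}
    counterfactual: {kind: at_least, threshold: 160}
  - factor: fruit
    cancer: stomach
    sexes: [male, female]
    rr: {value: 0.98, ci: [0.94, 1.02], increment: 100, form: continuous}
    counterfactual: {kind: at_least, threshold: 160}
  - factor: fruit
    cancer: lung
    sexes: [male, female]
    rr: {value: 0.92, ci: [0.89, 0.95], increment: 100, form: continuous}
    counterfactual: {kind: at_least, threshold: 160}
  - factor: citrus
    cancer: stomach_cardia
    sexes: [male, female]
    rr: {value: 0.87, ci: [0.76, 0.99], form: any_vs_none}
    counterfactual: {kind: any_intake}
  - factor: coffee
    cancer: liver
    sexes: [male, female]
    rr: {value: 0.66, ci: [0.55, 0.78], form: any_vs_none}
    counterfactual: {kind: any_intake}
  - factor: coffee
    cancer: endometrium
    sexes: [female]
    rr: {value: 0.87, ci: [0.79, 0.95], form: any_vs_none}
    counterfactual: {kind: any_intake}
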