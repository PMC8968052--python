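# Compact 10-node tiered ground truth for structure-recovery exercises:
# all-binary variables, at most three parents per node, strong effects so
# the structure is identifiable from moderate sample sizes.
variables:
  - {name: clinical_t, tier: 0, categories: [early, advanced], marginal: [0.45, 0.55]}
  - {name: clinical_n, tier: 0, categories: [negative, positive], marginal: [0.5, 0.5]}
  - {name: tumor_distance, tier: 0, categories: [low, high], marginal: [0.4, 0.6]}
  - {name: neoadjuvant_chemo, tier: 1, categories: ["no", "yes"], marginal: [0.35, 0.65]}
  - {name: rt_dose, tier: 1, categories: [low, high], marginal: [0.3, 0.7]}
  - {name: surgery_procedure, tier: 2, categories: [APR, AR], marginal: [0.35, 0.65]}
  - {name: pathological_t, tier: 3, categories: [low, high], marginal: [0.45, 0.55]}
  - {name: pathological_n, tier: 3, categories: [negative, positive], marginal: [0.4, 0.6]}
  - {name: crm, tier: 3, categories: [negative, positive], marginal: [0.55, 0.45]}

arcs:
  - [clinical_t, clinical_n, 0.7]
  - [clinical_t, neoadjuvant_chemo, 0.7]
  - [clinical_n, neoadjuvant_chemo, 0.7]
  - [clinical_t, rt_dose, 0.7]
  - [tumor_distance, surgery_procedure, 0.7]
  - [clinical_t, surgery_procedure, 0.7]
  - [neoadjuvant_chemo, pathological_t, 0.7]
  - [rt_dose, pathological_t, 0.7]
  - [clinical_n, pathological_n, 0.7]
  - [neoadjuvant_chemo, pathological_n, 0.7]
  - [pathological_t, crm, 0.9]

outcomes:
  - name: recurrence
    tier: 5
    prevalence: 0.3
    strength: 1.0
    parents: [crm, pathological_t, pathological_n]

missingness: {}

cohorts:
  trial_01: 10000
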