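# Default synthetic-cohort generator: a ground-truth Bayesian network over
# the full variable set, with category marginals, per-variable missingness
# fractions and outcome prevalences calibrated to the training-cohort
# characteristics table of the study population (renormalized over observed
# values). Dependencies follow the expert consensus structure plus a few
# tier-valid arcs touching the variables the experts excluded; each outcome
# node's parents are the six expert-structure outcome parents.
#
# CPT parameterization: each child row is the target marginal exponentially
# tilted by `strength * z_parent * z_child` (z = evenly spaced level scores
# in [-1, 1]), then calibrated so the implied marginal matches the target
# exactly. Outcome nodes use a logistic CPT whose intercept is solved so the
# marginal prevalence matches the target.

variables:
  - {name: age, tier: 0, categories: ["<50", "50-65", ">65"], marginal: [0.12, 0.53, 0.35]}
  - {name: gender, tier: 0, categories: [Male, Female], marginal: [0.70, 0.30]}
  - {name: clinical_t, tier: 1, categories: [cT1, cT2, cT3, cT4], marginal: [0.019, 0.080, 0.825, 0.076]}
  - {name: clinical_n, tier: 1, categories: [cN0, cN1, cN2], marginal: [0.435, 0.480, 0.085]}
  - {name: tumor_distance, tier: 1, categories: ["<=5cm", ">5cm"], marginal: [0.37, 0.63]}
  - {name: neoadjuvant_chemo, tier: 2, categories: [5FU+OXI, 5FUbased, NoChemo], marginal: [0.218, 0.542, 0.240]}
  - {name: rt_dose, tier: 2, categories: ["<=45Gy", ">45Gy"], marginal: [0.23, 0.77]}
  - {name: surgery_procedure, tier: 3, categories: [APR, ARbased, NoSurgery], marginal: [0.312, 0.668, 0.020]}
  - {name: overall_treatment_time, tier: 3, categories: ["<=38d", ">38d"], marginal: [0.56, 0.44]}
  - {name: pathological_t, tier: 4, categories: [ypT0, ypT1, ypT2, ypT3, ypT4], marginal: [0.126, 0.062, 0.292, 0.485, 0.035]}
  - {name: pathological_n, tier: 4, categories: [ypN0, ypN1, ypN2], marginal: [0.691, 0.246, 0.063]}
  - {name: crm, tier: 4, categories: [Negative, Positive], marginal: [0.555, 0.445]}
  - {name: adjuvant_chemo, tier: 5, categories: [5FU+OXI, 5FUbased, NoChemo], marginal: [0.126, 0.483, 0.391]}

arcs:
  - [clinical_t, clinical_n, 0.8]
  - [clinical_t, neoadjuvant_chemo, 0.8]
  - [clinical_n, neoadjuvant_chemo, 0.8]
  - [clinical_t, rt_dose, 0.8]
  - [clinical_n, rt_dose, 0.8]
  - [clinical_t, surgery_procedure, 0.8]
  - [tumor_distance, surgery_procedure, 0.8]
  - [clinical_t, pathological_t, 0.8]
  - [neoadjuvant_chemo, pathological_t, 0.8]
  - [rt_dose, pathological_t, 0.8]
  - [clinical_n, pathological_n, 0.8]
  - [neoadjuvant_chemo, pathological_n, 0.8]
  - [pathological_t, crm, 0.8]
  - [age, clinical_t, 0.4]
  - [age, surgery_procedure, 0.4]
  - [clinical_t, overall_treatment_time, 0.6]
  - [rt_dose, overall_treatment_time, 0.6]
  - [pathological_t, adjuvant_chemo, 0.6]
  - [pathological_n, adjuvant_chemo, 0.6]
  - [age, adjuvant_chemo, 0.4]

outcomes:
  # prevalence = events / (events + non-events) among complete outcomes
  - name: recurrence_2y
    tier: 6
    prevalence: 0.0846
    strength: 1.2
    parents: [crm, pathological_t, pathological_n, surgery_procedure, clinical_t, tumor_distance]
  - name: recurrence_3y
    tier: 6
    prevalence: 0.1239
    strength: 1.2
    parents: [crm, pathological_t, pathological_n, surgery_procedure, clinical_t, tumor_distance]
  - name: recurrence_5y
    tier: 6
    prevalence: 0.2273
    strength: 1.2
    parents: [crm, pathological_t, pathological_n, surgery_procedure, clinical_t, tumor_distance]

missingness:
  age: 0.017
  gender: 0.002
  clinical_t: 0.102
  clinical_n: 0.342
  rt_dose: 0.225
  surgery_procedure: 0.033
  crm: 0.819
  overall_treatment_time: 0.261
  neoadjuvant_chemo: 0.042
  tumor_distance: 0.167
  adjuvant_chemo: 0.043
  pathological_n: 0.080
  pathological_t: 0.080
  recurrence_2y: 0.158
  recurrence_3y: 0.272
  recurrence_5y: 0.512

# 14 synthetic trial cohorts; sizes are arbitrary but sum to 6754
cohorts:
  trial_01: 1200
  trial_02: 900
  trial_03: 800
  trial_04: 700
  trial_05: 600
  trial_06: 500
  trial_07: 450
  trial_08: 400
  trial_09: 350
  trial_10: 300
  trial_11: 250
  trial_12: 150
  trial_13: 104
  trial_14: 50
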