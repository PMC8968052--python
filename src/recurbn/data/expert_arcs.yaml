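# Expert consensus structure: the arc list that survived the full
# elicitation protocol (two independent proposals, intersection, unanimous
# two-reviewer filter, final validation). Transcribed from the published
# figure; editable so the transcription stays reviewable.
#
# 19 arcs over 10 variables; the outcome has 6 parents. Age, gender,
# adjuvant chemotherapy and overall treatment time are not touched by any
# arc and are therefore excluded from the structure.
arcs:
  - [clinical_t, clinical_n]
  - [clinical_t, neoadjuvant_chemo]
  - [clinical_n, neoadjuvant_chemo]
  - [clinical_t, rt_dose]
  - [clinical_n, rt_dose]
  - [clinical_t, surgery_procedure]
  - [tumor_distance, surgery_procedure]
  - [clinical_t, pathological_t]
  - [neoadjuvant_chemo, pathological_t]
  - [rt_dose, pathological_t]
  - [clinical_n, pathological_n]
  - [neoadjuvant_chemo, pathological_n]
  - [pathological_t, crm]
  - [crm, outcome]
  - [pathological_t, outcome]
  - [pathological_n, outcome]
  - [surgery_procedure, outcome]
  - [clinical_t, outcome]
  - [tumor_distance, outcome]
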