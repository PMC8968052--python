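# Clinical extraction timeline: tier index = when the variable becomes
# available in practice (baseline demographics -> diagnostic staging ->
# neoadjuvant treatment -> surgery -> pathology -> adjuvant treatment ->
# follow-up). Arcs may never point from a later tier to an earlier one;
# demographics precede staging, so staging -> age is invalid while
# age -> staging is admissible. "outcome" is a placeholder bound to one
# recurrence endpoint (2y/3y/5y) at run time; it occupies the final tier.
tiers:
  age: 0
  gender: 0
  clinical_t: 1
  clinical_n: 1
  tumor_distance: 1
  neoadjuvant_chemo: 2
  rt_dose: 2
  surgery_procedure: 3
  overall_treatment_time: 3
  pathological_t: 4
  pathological_n: 4
  crm: 4
  adjuvant_chemo: 5
  outcome: 6
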