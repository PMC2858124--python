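# Pioglitazone for type-2 diabetes, evaluated on the evidence available in
# 2001 (shortly after approval). Oral antidiabetics aim to prevent macro- and
# microvascular sequelae, so the therapeutic aim is prevention. The two
# pivotal trials tested pioglitazone as add-on to metformin or sulphonylurea
# against placebo, on the surrogate outcome HbA1c; both showed significant
# benefit. No NNT can be derived from HbA1c, so the efficiency score is not
# modified. The printed efficiency value (+4.0) uses half-up integer rounding.
schema_version: 1
context:
  drug_name: pioglitazone
  atc_code: A10BG03
  indication: diabetes mellitus type 2
  icd10_code: E10-E14
  therapeutic_aim: prevention
  disease_category: I
  established_therapies:
    - metformin
    - sulphonylureas
trials:
  - trial_id: PIO-ADDON-MET
    comparator_kind: placebo_add_on
    outcome_level: surrogate
    result: superiority
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
  - trial_id: PIO-ADDON-SU
    comparator_kind: placebo_add_on
    outcome_level: surrogate
    result: superiority
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
# Both arms showed severe (grade 3) and mild-to-moderate (grades 1+2) adverse
# events at below 10%, i.e. the same frequency class, so the AE rows cancel.
# The SPC reports interactions with gemfibrozil and rifampicin that may
# require dose changes of pioglitazone; placebo has zero interaction
# potential.
drug_risk:
  arm_label: pioglitazone add-on
  grade_4_5_freq: zero
  grade_3_freq: 1_to_10
  grade_1_2_freq: 1_to_10
  interaction_class: dose_change
comparator_risk:
  arm_label: placebo add-on
  grade_4_5_freq: zero
  grade_3_freq: 1_to_10
  grade_1_2_freq: 1_to_10
  interaction_class: unlikely_or_none
options:
  rounding: half_up_integer
  yellow_half_width: 2.0
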