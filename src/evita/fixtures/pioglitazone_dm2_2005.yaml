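# Pioglitazone for type-2 diabetes, re-evaluated in 2005 after publication of
# the PROactive outcome trial (pioglitazone vs placebo on top of established
# therapy, patient-relevant composite endpoint). PROactive failed to show
# superiority; patient-relevant evidence supersedes the two earlier surrogate
# (HbA1c) trials, so the efficiency score drops to zero. The risk
# reconciliation is unchanged (-1.0 from the interaction row), turning the
# total slightly negative.
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
  - trial_id: PROactive
    comparator_kind: placebo_add_on
    outcome_level: patient_relevant
    result: no_significant_difference
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
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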