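# Zoledronic acid (5 mg annually) for postmenopausal osteoporosis. Both
# published trials (a dose-efficiency study on bone mineral density and the
# pivotal HORIZON fracture trial) compared against placebo alone although
# established therapies exist (oral bisphosphonates, raloxifene, estrogens),
# so neither qualifies: the verdict is N/A, rendered as a yield sign. The
# risk profiles below are recorded for completeness but are never scored.
schema_version: 1
context:
  drug_name: zoledronic acid (5 mg annually)
  atc_code: M05BA08
  indication: postmenopausal osteoporosis at high risk of fracture
  icd10_code: M81
  therapeutic_aim: treatment
  disease_category: I
  established_therapies:
    - alendronic acid
    - risedronic acid
    - raloxifene
    - estrogens
trials:
  - trial_id: ZOL-BMD-DOSE
    comparator_kind: placebo_only
    outcome_level: surrogate
    result: superiority
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
  - trial_id: HORIZON
    comparator_kind: placebo_only
    outcome_level: patient_relevant
    result: superiority
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
drug_risk:
  arm_label: zoledronic acid
  grade_4_5_freq: 0.1_to_1
  grade_3_freq: 1_to_10
  grade_1_2_freq: 10_plus
  interaction_class: no_information
comparator_risk:
  arm_label: placebo
  grade_4_5_freq: 0.1_to_1
  grade_3_freq: 1_to_10
  grade_1_2_freq: 10_plus
  interaction_class: unlikely_or_none
options:
  rounding: none
  yellow_half_width: 2.0
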