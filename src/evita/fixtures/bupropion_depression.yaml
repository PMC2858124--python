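# Bupropion for episodes of major depression. Three head-to-head trials
# against established antidepressants (paroxetine, venlafaxine) qualified;
# all used depression scale scores (HAMD-17, MADRS), which count as
# surrogate outcomes. No trial showed superiority; one showed inferiority to
# venlafaxine and two showed equivalence. Scale scores admit no NNT, so the
# efficiency sum stands unmodified (and unrounded, as printed: -1.25).
schema_version: 1
context:
  drug_name: bupropion
  atc_code: N06AX12
  indication: episodes of major depression
  icd10_code: F32-F39
  therapeutic_aim: treatment
  disease_category: I
  established_therapies:
    - paroxetine
    - venlafaxine
trials:
  - trial_id: BUP-PAROX-HAMD
    comparator_kind: head_to_head
    outcome_level: surrogate
    result: non_inferiority_or_equivalence
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
  - trial_id: BUP-VENLA-MADRS-1
    comparator_kind: head_to_head
    outcome_level: surrogate
    result: non_inferiority_or_equivalence
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
  - trial_id: BUP-VENLA-MADRS-2
    comparator_kind: head_to_head
    outcome_level: surrogate
    result: inferiority
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
# Trial AE reporting was incomplete, so the risk profiles come from the SPCs
# of bupropion and its comparators. All three compounds feature grade 1+2 and
# grade 3 AEs very commonly (>=10%), grade 4+5 AEs less commonly (0.1 to <1%)
# and occasional interactions with possible clinical consequences: identical
# sums of -7.5 per arm, hence a net risk score of zero.
drug_risk:
  arm_label: bupropion
  grade_4_5_freq: 0.1_to_1
  grade_3_freq: 10_plus
  grade_1_2_freq: 10_plus
  interaction_class: occasional_or_clinical
comparator_risk:
  arm_label: paroxetine / venlafaxine
  grade_4_5_freq: 0.1_to_1
  grade_3_freq: 10_plus
  grade_1_2_freq: 10_plus
  interaction_class: occasional_or_clinical
options:
  rounding: none
  yellow_half_width: 2.0
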