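# Lenalidomide (+ dexamethasone) for refractory or relapsing multiple myeloma.
# Two pivotal trials ran under an identical protocol and count as one logical
# trial; lenalidomide was compared with placebo on top of high-dose
# dexamethasone (add-on), with a patient-relevant outcome. The NNT of 2.6 was
# observed over 1.5 years and derives from the overall-response secondary
# outcome (time to progression admits no NNT).
schema_version: 1
context:
  drug_name: lenalidomide
  atc_code: L04AX04
  indication: refractory or relapsing multiple myeloma (after >=1 previous therapy)
  icd10_code: C90
  therapeutic_aim: treatment
  disease_category: I
  established_therapies:
    - high-dose dexamethasone
    - anthracycline-based chemotherapy
    - bendamustine
    - cyclophosphamide
    - bortezomib
    - second autologous stem cell transplantation
trials:
  - trial_id: MM-009
    comparator_kind: placebo_add_on
    outcome_level: patient_relevant
    result: superiority
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
    duration_years: 1.5
    nnt: 2.6
    duplicate_protocol_key: mm009-mm010-protocol
    nnt_provenance: overall response rate (secondary outcome), assumed positively
      correlated with time to progression
  - trial_id: MM-010
    comparator_kind: placebo_add_on
    outcome_level: patient_relevant
    result: superiority
    jadad:
      randomization_mentioned: true
      randomization_appropriate: appropriate
      blinding_mentioned: true
      blinding_appropriate: appropriate
      withdrawals_described: true
    duration_years: 1.5
    nnt: 2.6
    duplicate_protocol_key: mm009-mm010-protocol
# Adverse-event frequencies were very similar in both arms (same frequency
# class in every severity group; grade-3 events only slightly rarer under
# placebo, which does not cross a class boundary). Lenalidomide carries a
# clinically relevant interaction risk; for placebo the interaction potential
# is zero by definition.
drug_risk:
  arm_label: lenalidomide + dexamethasone
  grade_4_5_freq: 1_to_10
  grade_3_freq: 10_plus
  grade_1_2_freq: 10_plus
  interaction_class: occasional_or_clinical
comparator_risk:
  arm_label: placebo + dexamethasone
  grade_4_5_freq: 1_to_10
  grade_3_freq: 10_plus
  grade_1_2_freq: 10_plus
  interaction_class: unlikely_or_none
options:
  rounding: none
  yellow_half_width: 2.0
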