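"""Build an assessment dossier directly in Python and score it.

A hypothetical treatment drug with one patient-relevant superiority trial
(NNT 4 over 2 years, i.e. 8 per year -> modifier 1.5) and a slightly
cleaner AE profile than its comparator. The printed breakdown shows how
each rubric component contributes to the total.
"""

from evita import (
    ArmRiskProfile,
    AssessmentDossier,
    TherapeuticContext,
    TrialRecord,
    evaluate,
)

dossier = AssessmentDossier(
    context=TherapeuticContext(
        drug_name="examplinib",
        indication="hypothetical severe chronic disease",
        therapeutic_aim="treatment",
        disease_category="I",
        established_therapies=["standard of care"],
    ),
    trials=[
        TrialRecord(
            trial_id="EX-301",
            comparator_kind="head_to_head",
            outcome_level="patient_relevant",
            result="superiority",
            jadad=5,
            nnt=4.0,
            duration_years=2.0,
        ),
    ],
    drug_risk=ArmRiskProfile(
        arm_label="examplinib",
        grade_4_5_freq="below_0.1",
        grade_3_freq="1_to_10",
        grade_1_2_freq="10_plus",
        interaction_class="dose_change",
    ),
    comparator_risk=ArmRiskProfile(
        arm_label="standard of care",
        grade_4_5_freq="0.1_to_1",
        grade_3_freq="10_plus",
        grade_1_2_freq="10_plus",
        interaction_class="occasional_or_clinical",
    ),
)

result = evaluate(dossier)
eff, risk = result.efficiency, result.risk
print(f"setting: {result.setting.value.value}")
print(f"efficiency: base {eff.base_sum:+g} x modifier {eff.modifier} = {eff.reported_score:+g}")
print(f"risk: drug {risk.drug_sum:+g} vs comparator {risk.comparator_sum:+g} -> net {risk.net_score:+g}")
print(f"EVITA score: {result.total:+g} ({result.band.value})")
# The positive net risk shows the comparator's worse AE/interaction profile
# counterbalancing: the drug gains points it did not earn through efficacy.
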