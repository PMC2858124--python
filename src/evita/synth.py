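"""Random but schema-valid assessment dossiers, for testing and fuzzing.

The generator is purely synthetic: it samples every enum literal with
positive probability and exercises the structural corners of the schema
(precomputed vs itemized Jadad, NNT vs ARR strength data, duplicate
protocol keys, assessor exclusion notes, empty trial lists), but it makes
no attempt to mimic the joint distribution of real trial programmes.
"""

from __future__ import annotations

import random

from .model import (
    ArmRiskProfile,
    AssessmentDossier,
    ComparatorKind,
    DiseaseCategory,
    FrequencyClass,
    InteractionClass,
    ItemQuality,
    JadadItems,
    OutcomeLevel,
    RoundingMode,
    ScoringOptions,
    TherapeuticAim,
    TherapeuticContext,
    TrialRecord,
    TrialResult,
)

__all__ = ["generate_synthetic_dossier"]

_THERAPIES = ["standard therapy A", "standard therapy B", "standard therapy C"]


def _jadad_items(rng: random.Random) -> JadadItems:
    rand_mentioned = rng.random() < 0.8
    blind_mentioned = rng.random() < 0.7
    qualities = list(ItemQuality)
    return JadadItems(
        randomization_mentioned=rand_mentioned,
        randomization_appropriate=rng.choice(qualities) if rand_mentioned else ItemQuality.NOT_DESCRIBED,
        blinding_mentioned=blind_mentioned,
        blinding_appropriate=rng.choice(qualities) if blind_mentioned else ItemQuality.NOT_DESCRIBED,
        withdrawals_described=rng.random() < 0.7,
    )


def _trial(rng: random.Random, index: int, duplicate_key: str | None) -> TrialRecord:
    nnt = arr = duration = None
    strength = rng.random()
    if strength < 0.4:  # NNT recorded
        nnt = round(rng.uniform(1.0, 400.0), 1)
        duration = round(rng.uniform(0.25, 5.0), 2) if rng.random() < 0.8 else None
    elif strength < 0.6:  # ARR recorded instead
        arr = round(rng.uniform(0.005, 1.0), 3)
    return TrialRecord(
        trial_id=f"TRIAL-{index:03d}",
        comparator_kind=rng.choice(list(ComparatorKind)),
        outcome_level=rng.choice(list(OutcomeLevel)),
        result=rng.choice(list(TrialResult)),
        jadad=rng.randint(0, 5) if rng.random() < 0.5 else _jadad_items(rng),
        duration_years=duration,
        nnt=nnt,
        arr=arr,
        duplicate_protocol_key=duplicate_key,
        exclusion_note="assessor exclusion (synthetic)" if rng.random() < 0.1 else None,
    )


def _arm(rng: random.Random, label: str) -> ArmRiskProfile:
    def freq() -> FrequencyClass | float:
        if rng.random() < 0.5:
            return rng.choice(list(FrequencyClass))
        return round(rng.uniform(0.0, 40.0), 2)

    return ArmRiskProfile(
        arm_label=label,
        grade_4_5_freq=freq(),
        grade_3_freq=freq(),
        grade_1_2_freq=freq(),
        interaction_class=rng.choice(list(InteractionClass)),
    )


def generate_synthetic_dossier(seed: int, n_trials: int = 3) -> AssessmentDossier:
    """Generate a deterministic, schema-valid random dossier.

    Parameters
    ----------
    seed
        Seeds the private RNG; equal seeds give identical dossiers.
    n_trials
        Number of trial records (0 is allowed and yields a dossier whose
        evaluation verdict is N/A).
    """
    if n_trials < 0:
        raise ValueError(f"n_trials must be >= 0, got {n_trials}")
    rng = random.Random(seed)
    context = TherapeuticContext(
        drug_name=f"synthetic-drug-{seed}",
        atc_code="X00XX00" if rng.random() < 0.5 else None,
        indication="synthetic indication",
        icd10_code="Z00" if rng.random() < 0.5 else None,
        therapeutic_aim=rng.choice(list(TherapeuticAim)),
        disease_category=rng.choice(list(DiseaseCategory)),
        established_therapies=_THERAPIES[: rng.randint(0, len(_THERAPIES))],
    )
    # Occasionally share one protocol key across two trials so the
    # duplicate-collapse path is exercised.
    duplicate_slots: set[int] = set()
    if n_trials >= 2 and rng.random() < 0.3:
        duplicate_slots = set(rng.sample(range(n_trials), 2))
    trials = [
        _trial(rng, i, f"PROTO-{seed}" if i in duplicate_slots else None)
        for i in range(n_trials)
    ]
    return AssessmentDossier(
        context=context,
        trials=trials,
        drug_risk=_arm(rng, context.drug_name),
        comparator_risk=_arm(rng, "comparator"),
        options=ScoringOptions(
            rounding=rng.choice(list(RoundingMode)),
            yellow_half_width=2.0,
        ),
    )
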