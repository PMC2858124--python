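"""Trial eligibility: Jadad quality scoring, inclusion/exclusion rules and
the A1/A2/B1/B2/N-A trial-setting classification.

An RCT enters the evaluation only if it scores at least 3 on the Jadad
quality instrument and uses an acceptable comparator: placebo alone is
admissible only when no established therapy exists, or when the study drug
and placebo are both given on top of established therapy (add-on design).
Trials run under an identical protocol count as one logical trial, and
once patient-relevant evidence exists, surrogate-outcome trials no longer
contribute to efficiency counting.
"""

from __future__ import annotations

from typing import Union

from pydantic import BaseModel, ConfigDict

from .model import (
    ComparatorKind,
    ItemQuality,
    JadadItems,
    OutcomeLevel,
    TherapeuticContext,
    TrialRecord,
)

__all__ = [
    "SettingValue",
    "TrialSetting",
    "ExcludedTrial",
    "compute_jadad",
    "trial_jadad",
    "filter_trials",
    "classify_trial_setting",
]

import enum

JADAD_THRESHOLD = 3

REASON_QUALITY = "quality"
REASON_PLACEBO = "placebo despite established therapy"
REASON_DUPLICATE = "duplicate protocol"
REASON_SUPERSEDED = "superseded by patient-relevant evidence"


class SettingValue(str, enum.Enum):
    A1 = "A1"  # patient-relevant outcomes, head-to-head vs established therapy
    A2 = "A2"  # patient-relevant outcomes, placebo comparison (incl. add-on)
    B1 = "B1"  # surrogate outcomes, head-to-head
    B2 = "B2"  # surrogate outcomes, placebo comparison
    NA = "NA"  # no eligible trials: score not computable


class ExcludedTrial(BaseModel):
    model_config = ConfigDict(frozen=True)
    trial_id: str
    reason: str


class TrialSetting(BaseModel):
    """Classification outcome plus the audit trail of in/exclusions."""

    model_config = ConfigDict(frozen=True)

    value: SettingValue
    included_trials: list[str]
    excluded_trials: list[ExcludedTrial]


def compute_jadad(items: JadadItems) -> int:
    """Jadad quality score (0-5) from the five instrument items.

    One point each for randomization mentioned, blinding mentioned and
    withdrawals/dropouts described; one extra point when the randomization
    or blinding method is appropriate, one deducted when it is
    inappropriate.  The score is clamped at 0.
    """
    score = 0
    if items.randomization_mentioned:
        score += 1
        if items.randomization_appropriate == ItemQuality.APPROPRIATE:
            score += 1
        elif items.randomization_appropriate == ItemQuality.INAPPROPRIATE:
            score -= 1
    if items.blinding_mentioned:
        score += 1
        if items.blinding_appropriate == ItemQuality.APPROPRIATE:
            score += 1
        elif items.blinding_appropriate == ItemQuality.INAPPROPRIATE:
            score -= 1
    if items.withdrawals_described:
        score += 1
    return max(score, 0)


def trial_jadad(trial: TrialRecord) -> int:
    """Jadad score of a trial, whether itemized or precomputed."""
    if isinstance(trial.jadad, JadadItems):
        return compute_jadad(trial.jadad)
    return trial.jadad


def filter_trials(
    trials: list[TrialRecord], context: TherapeuticContext
) -> tuple[list[TrialRecord], list[tuple[TrialRecord, str]]]:
    """Apply the EVITA inclusion rules.

    Returns ``(included, excluded)`` where ``excluded`` pairs each dropped
    trial with its reason.  Rules, in order:

    1. assessor-recorded exclusions (``exclusion_note``, e.g. GCP concerns);
    2. Jadad score below 3 ("quality");
    3. pure placebo comparison although established therapies exist;
    4. collapse of trials sharing a ``duplicate_protocol_key`` into one
       logical trial (the first in dossier order is kept);
    5. supersession: once any included trial has a patient-relevant
       outcome, surrogate-outcome trials are removed from efficiency
       counting (they may still inform the risk profiles).

    ``included`` and ``excluded`` partition the input.
    """
    included: list[TrialRecord] = []
    excluded: list[tuple[TrialRecord, str]] = []
    seen_protocols: set[str] = set()

    for trial in trials:
        if trial.exclusion_note is not None:
            excluded.append((trial, trial.exclusion_note))
            continue
        if trial_jadad(trial) < JADAD_THRESHOLD:
            excluded.append((trial, REASON_QUALITY))
            continue
        if (
            trial.comparator_kind == ComparatorKind.PLACEBO_ONLY
            and context.established_therapies
        ):
            excluded.append((trial, REASON_PLACEBO))
            continue
        key = trial.duplicate_protocol_key
        if key is not None:
            if key in seen_protocols:
                excluded.append((trial, REASON_DUPLICATE))
                continue
            seen_protocols.add(key)
        included.append(trial)

    if any(t.outcome_level == OutcomeLevel.PATIENT_RELEVANT for t in included):
        surrogate = [t for t in included if t.outcome_level == OutcomeLevel.SURROGATE]
        included = [t for t in included if t.outcome_level == OutcomeLevel.PATIENT_RELEVANT]
        excluded.extend((t, REASON_SUPERSEDED) for t in surrogate)

    return included, excluded


def classify_trial_setting(
    included: list[TrialRecord],
    context: TherapeuticContext,
    excluded: Union[list[tuple[TrialRecord, str]], None] = None,
) -> TrialSetting:
    """Classify the trial setting from the already-filtered evidence.

    No eligible trial -> N/A.  Otherwise the letter is A when any included
    trial addresses patient-relevant outcomes, else B; the digit is 1 when
    any trial at that outcome level is a head-to-head comparison with
    established therapy (head-to-head dominates mixed designs), else 2
    (placebo comparison: add-on, or direct when no established therapy
    exists).
    """
    audit = [ExcludedTrial(trial_id=t.trial_id, reason=r) for t, r in (excluded or [])]
    if not included:
        return TrialSetting(value=SettingValue.NA, included_trials=[], excluded_trials=audit)

    patient_relevant = any(
        t.outcome_level == OutcomeLevel.PATIENT_RELEVANT for t in included
    )
    tier_level = OutcomeLevel.PATIENT_RELEVANT if patient_relevant else OutcomeLevel.SURROGATE
    tier_trials = [t for t in included if t.outcome_level == tier_level]
    head_to_head = any(
        t.comparator_kind == ComparatorKind.HEAD_TO_HEAD for t in tier_trials
    )
    value = {
        (True, True): SettingValue.A1,
        (True, False): SettingValue.A2,
        (False, True): SettingValue.B1,
        (False, False): SettingValue.B2,
    }[(patient_relevant, head_to_head)]
    return TrialSetting(
        value=value,
        included_trials=[t.trial_id for t in included],
        excluded_trials=audit,
    )
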