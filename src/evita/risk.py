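"""Comparative risk scoring from CTCAE severity groups, SPC frequency
classes and interaction potential.

Each arm accrues negative points for the worst single adverse event (AE)
in each of three CTCAE severity groups — grades 4+5 (life-threatening,
disabling or fatal), grade 3 (severe), grades 1+2 (mild/moderate) — scored
by SPC frequency class, plus an interaction penalty.  The net risk score
opposes the investigational arm's sum to the comparator's, so a drug with
a cleaner profile than its comparator can score positive points.
"""

from __future__ import annotations

from typing import Union

from pydantic import BaseModel, ConfigDict

from .model import ArmRiskProfile, FrequencyClass, InteractionClass

__all__ = [
    "SeverityGroup",
    "RiskResult",
    "frequency_class",
    "severity_points",
    "interaction_points",
    "arm_sum",
    "risk_score",
]

import enum


class SeverityGroup(str, enum.Enum):
    GRADES_4_5 = "grades_4_5"
    GRADE_3 = "grade_3"
    GRADES_1_2 = "grades_1_2"


# Penalty per severity group and frequency class. Grade 4/5 events are the
# only ones penalized even when rarer than 0.1%.
_SEVERITY_TABLE: dict[SeverityGroup, dict[FrequencyClass, float]] = {
    SeverityGroup.GRADES_4_5: {
        FrequencyClass.FROM_10: -4.0,
        FrequencyClass.FROM_1_TO_10: -3.0,
        FrequencyClass.FROM_0_1_TO_1: -2.0,
        FrequencyClass.BELOW_0_1: -1.0,
        FrequencyClass.ZERO: 0.0,
    },
    SeverityGroup.GRADE_3: {
        FrequencyClass.FROM_10: -2.5,
        FrequencyClass.FROM_1_TO_10: -2.0,
        FrequencyClass.FROM_0_1_TO_1: -1.0,
        FrequencyClass.BELOW_0_1: 0.0,
        FrequencyClass.ZERO: 0.0,
    },
    SeverityGroup.GRADES_1_2: {
        FrequencyClass.FROM_10: -1.5,
        FrequencyClass.FROM_1_TO_10: -1.0,
        FrequencyClass.FROM_0_1_TO_1: -0.5,
        FrequencyClass.BELOW_0_1: 0.0,
        FrequencyClass.ZERO: 0.0,
    },
}

_INTERACTION_TABLE: dict[InteractionClass, float] = {
    InteractionClass.FREQUENT_OR_SERIOUS: -2.0,
    InteractionClass.OCCASIONAL_OR_CLINICAL: -1.5,
    InteractionClass.DOSE_CHANGE: -1.0,
    InteractionClass.UNLIKELY_OR_NONE: 0.0,
    InteractionClass.NO_INFORMATION: -1.0,
}


class ArmBreakdown(BaseModel):
    model_config = ConfigDict(frozen=True)
    arm_label: str
    grade_4_5: float
    grade_3: float
    grade_1_2: float
    interaction: float
    total: float


class RiskResult(BaseModel):
    """Net risk score with both arms' point breakdowns."""

    model_config = ConfigDict(frozen=True)

    drug_sum: float
    comparator_sum: float
    net_score: float
    drug_breakdown: ArmBreakdown
    comparator_breakdown: ArmBreakdown


def frequency_class(percent: float) -> FrequencyClass:
    """Map an AE percentage to its SPC frequency class.

    Classes: exactly 0 (no events), rare/very rare (below 0.1%), less
    common (0.1 to below 1%), common (1 to below 10%) and very common
    (10% and above); lower bounds inclusive.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must lie in [0, 100], got {percent}")
    if percent == 0.0:
        return FrequencyClass.ZERO
    if percent < 0.1:
        return FrequencyClass.BELOW_0_1
    if percent < 1.0:
        return FrequencyClass.FROM_0_1_TO_1
    if percent < 10.0:
        return FrequencyClass.FROM_1_TO_10
    return FrequencyClass.FROM_10


def _as_class(value: Union[FrequencyClass, float]) -> FrequencyClass:
    if isinstance(value, FrequencyClass):
        return value
    return frequency_class(value)


def severity_points(group: SeverityGroup, freq: Union[FrequencyClass, float]) -> float:
    """Penalty (<= 0) for the worst AE of a severity group at a given
    frequency class (or percent, classified on the fly)."""
    return _SEVERITY_TABLE[group][_as_class(freq)]


def interaction_points(cls: InteractionClass) -> float:
    """Penalty (<= 0) for the drug-interaction potential; absent
    information is penalized like a mandatory dose change."""
    return _INTERACTION_TABLE[cls]


def _breakdown(profile: ArmRiskProfile) -> ArmBreakdown:
    g45 = severity_points(SeverityGroup.GRADES_4_5, profile.grade_4_5_freq)
    g3 = severity_points(SeverityGroup.GRADE_3, profile.grade_3_freq)
    g12 = severity_points(SeverityGroup.GRADES_1_2, profile.grade_1_2_freq)
    inter = interaction_points(profile.interaction_class)
    return ArmBreakdown(
        arm_label=profile.arm_label,
        grade_4_5=g45,
        grade_3=g3,
        grade_1_2=g12,
        interaction=inter,
        total=g45 + g3 + g12 + inter,
    )


def arm_sum(profile: ArmRiskProfile) -> float:
    """Point sum for one arm: three severity penalties plus the
    interaction penalty; ranges from -10.0 to 0."""
    return _breakdown(profile).total


def risk_score(drug: ArmRiskProfile, comparator: ArmRiskProfile) -> RiskResult:
    """Net risk score: the drug arm's sum opposed to the comparator's.

    Positive when the comparator's profile is worse than the drug's.
    Resolution is the frequency class, not the raw percentage: arms whose
    worst AEs fall in the same class contribute nothing to the net score.
    """
    d = _breakdown(drug)
    c = _breakdown(comparator)
    return RiskResult(
        drug_sum=d.total,
        comparator_sum=c.total,
        net_score=d.total - c.total,
        drug_breakdown=d,
        comparator_breakdown=c,
    )
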