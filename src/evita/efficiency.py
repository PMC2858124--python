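"""Efficiency scoring: base points by result direction and trial count,
strengthened or damped by the NNT modifier.

Superiority in one RCT with patient-relevant outcomes is worth +5.0
points, in two or more +7.5; inferiority mirrors these negatively.
Non-inferiority/equivalence trials only matter in the presence of
directional evidence: they attenuate a superiority result (-5/3 for one
trial, -2.5 for two or more) and soften an inferiority result by the same
amounts with opposite sign.  All magnitudes are halved when the evidence
base consists of surrogate outcomes only.  The signed sum is then
multiplied by a modifier keyed on the annualized number needed to treat
(NNT), with separate bands for prevention and treatment aims.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .model import (
    OutcomeLevel,
    RoundingMode,
    ScoringOptions,
    TherapeuticAim,
    TherapeuticContext,
    TrialRecord,
    TrialResult,
)

__all__ = [
    "EfficiencyResult",
    "base_points",
    "annualize_nnt",
    "modifier_lookup",
    "efficiency_score",
]

# Patient-relevant cell values; surrogate outcomes halve each magnitude.
# The one-trial non-inferiority adjustment is exactly one third of the
# two-trial superiority step (5/3, printed rounded as 1.67).
_SUP_POINTS = (0.0, 5.0, 7.5)  # index min(n, 2)
_NONINF_POINTS = (0.0, 5.0 / 3.0, 2.5)

# Modifier bands: (inclusive lower NNT bound, factor), evaluated top-down.
_PREVENTION_BANDS = (
    (1000.0, 0.25),
    (500.0, 0.5),
    (300.0, 0.75),
    (175.0, 1.0),
    (100.0, 1.25),
    (50.0, 1.5),
    (20.0, 1.75),
    (1.0, 2.0),
)
_TREATMENT_BANDS = (
    (10.0, 1.0),
    (3.0, 1.5),
    (1.0, 2.0),
)

MODIFIER_VALUES = tuple(sorted({f for _, f in _PREVENTION_BANDS + _TREATMENT_BANDS}))


class EfficiencyResult(BaseModel):
    """Efficiency score with every intermediate retained for the audit trail."""

    model_config = ConfigDict(frozen=True)

    n_superiority: int
    n_noninferiority: int
    n_inferiority: int
    outcome_level_used: OutcomeLevel
    base_sum: float
    modifier: Optional[float] = None
    raw_score: float
    reported_score: float
    notes: list[str] = []


def base_points(
    n_sup: int, n_noninf: int, n_inf: int, level: OutcomeLevel
) -> float:
    """Signed base-point sum for a set of same-outcome-level RCTs.

    ``n_sup``/``n_noninf``/``n_inf`` count trials showing superiority,
    non-inferiority or equivalence, and inferiority.  Trials that merely
    failed to show a significant difference are counted in none of the
    three and contribute nothing.
    """
    if min(n_sup, n_noninf, n_inf) < 0:
        raise ValueError("trial counts must be non-negative")
    sup = _SUP_POINTS[min(n_sup, 2)]
    inf = -_SUP_POINTS[min(n_inf, 2)]
    directional = sup + inf
    if n_noninf == 0 or directional == 0.0:
        # "in the absence of other RCT" the equivalence row scores zero;
        # likewise when superiority and inferiority evidence cancel.
        noninf = 0.0
    elif directional > 0:
        noninf = -_NONINF_POINTS[min(n_noninf, 2)]
    else:
        noninf = _NONINF_POINTS[min(n_noninf, 2)]
    total = sup + inf + noninf
    if level == OutcomeLevel.SURROGATE:
        total /= 2.0
    return total


def annualize_nnt(nnt: float, duration_years: float) -> float:
    """Convert an NNT observed over ``duration_years`` to a per-year NNT.

    The absolute risk reduction is assumed to accrue linearly, so the ARR
    per year is the total ARR divided by the duration and the per-year NNT
    is ``nnt * duration_years`` (e.g. an NNT of 2.6 over 1.5 years is 3.9,
    roughly 4, per year).
    """
    if nnt < 1:
        raise ValueError(f"nnt must be >= 1, got {nnt}")
    if duration_years <= 0:
        raise ValueError(f"duration_years must be positive, got {duration_years}")
    return nnt * duration_years


def modifier_lookup(aim: TherapeuticAim, nnt_per_year: float) -> float:
    """Strength-of-effect modifier for a given therapeutic aim and
    annualized NNT.

    Prevention spans eight bands from 2.0 (NNT below 20) down to 0.25
    (NNT of 1000 or more); treatment uses three (2.0 below NNT 3, 1.5 up
    to below 10, 1.0 from 10 on).  Bands are half-open with the lower
    bound inclusive.
    """
    if nnt_per_year < 1:
        raise ValueError(f"nnt_per_year must be >= 1, got {nnt_per_year}")
    bands = _PREVENTION_BANDS if aim == TherapeuticAim.PREVENTION else _TREATMENT_BANDS
    for lower, factor in bands:
        if nnt_per_year >= lower:
            return factor
    raise AssertionError("unreachable: bands cover [1, inf)")


def _round_reported(raw: float, mode: RoundingMode) -> float:
    if mode == RoundingMode.HALF_UP_INTEGER:
        return float(Decimal(repr(raw)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return raw


def efficiency_score(
    included_trials: list[TrialRecord],
    context: TherapeuticContext,
    options: Optional[ScoringOptions] = None,
) -> EfficiencyResult:
    """Efficiency score of an already-filtered evidence set.

    Results are counted by direction, the base sum taken from the scoring
    grid at the evidence set's outcome level, and the sum multiplied by the
    NNT modifier when any superiority trial recorded a strength of effect
    (the smallest annualized NNT across superiority trials is used).  When
    no NNT is available the modifier is absent and the sum stands.
    """
    options = options or ScoringOptions()
    notes: list[str] = []
    n_sup = sum(1 for t in included_trials if t.result == TrialResult.SUPERIORITY)
    n_noninf = sum(
        1 for t in included_trials if t.result == TrialResult.NON_INFERIORITY_OR_EQUIVALENCE
    )
    n_inf = sum(1 for t in included_trials if t.result == TrialResult.INFERIORITY)
    n_nsd = len(included_trials) - n_sup - n_noninf - n_inf
    if n_nsd:
        notes.append(
            f"{n_nsd} trial(s) showed no significant difference and contribute 0 points"
        )

    level = (
        OutcomeLevel.PATIENT_RELEVANT
        if any(t.outcome_level == OutcomeLevel.PATIENT_RELEVANT for t in included_trials)
        else OutcomeLevel.SURROGATE
    )
    base = base_points(n_sup, n_noninf, n_inf, level)

    modifier: Optional[float] = None
    candidates: list[tuple[float, str]] = []
    for t in included_trials:
        if t.result != TrialResult.SUPERIORITY or t.effective_nnt is None:
            continue
        if t.duration_years is not None:
            candidates.append((annualize_nnt(t.effective_nnt, t.duration_years), t.trial_id))
        else:
            candidates.append((t.effective_nnt, t.trial_id))
            notes.append(
                f"{t.trial_id}: no duration recorded; NNT {t.effective_nnt:g} taken as per-year"
            )
    if candidates:
        nnt_year, source = min(candidates)
        modifier = modifier_lookup(context.therapeutic_aim, nnt_year)
        notes.append(
            f"modifier {modifier:g} from annualized NNT {nnt_year:g} ({source}, "
            f"aim {context.therapeutic_aim.value})"
        )
    elif base != 0.0:
        notes.append("no NNT available; efficiency score not modified further")

    raw = base * (modifier if modifier is not None else 1.0)
    return EfficiencyResult(
        n_superiority=n_sup,
        n_noninferiority=n_noninf,
        n_inferiority=n_inf,
        outcome_level_used=level,
        base_sum=base,
        modifier=modifier,
        raw_score=raw,
        reported_score=_round_reported(raw, options.rounding),
        notes=notes,
    )
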