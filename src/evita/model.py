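"""Domain model for EVITA assessment dossiers.

An assessment dossier captures everything needed to rate one drug in one
indication: the therapeutic context (aim, disease-severity category,
established alternatives), the randomized controlled trials (RCTs) that
constitute the evidence base, and the comparative adverse-event (AE) and
interaction profiles of the two arms.  All types validate their own
invariants on construction, so downstream scoring can assume clean input.
"""

from __future__ import annotations

import enum
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

SCHEMA_VERSION = 1


class TherapeuticAim(str, enum.Enum):
    """Goal of the therapy; selects the NNT modifier table."""

    PREVENTION = "prevention"
    TREATMENT = "treatment"


class DiseaseCategory(str, enum.Enum):
    """Severity grading of the disease (I worst .. IV outside treatment).

    The category annotates the assessment but never enters the score.
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class ComparatorKind(str, enum.Enum):
    HEAD_TO_HEAD = "head_to_head"
    PLACEBO_ADD_ON = "placebo_add_on"
    PLACEBO_ONLY = "placebo_only"


class OutcomeLevel(str, enum.Enum):
    PATIENT_RELEVANT = "patient_relevant"
    SURROGATE = "surrogate"


class TrialResult(str, enum.Enum):
    SUPERIORITY = "superiority"
    NON_INFERIORITY_OR_EQUIVALENCE = "non_inferiority_or_equivalence"
    INFERIORITY = "inferiority"
    #: Failed superiority trial without a formal equivalence claim; carries
    #: zero efficiency points but can still define the trial setting.
    NO_SIGNIFICANT_DIFFERENCE = "no_significant_difference"


class ItemQuality(str, enum.Enum):
    APPROPRIATE = "appropriate"
    INAPPROPRIATE = "inappropriate"
    NOT_DESCRIBED = "not_described"


class InteractionClass(str, enum.Enum):
    """Drug-drug interaction potential, usually taken from the SPC."""

    FREQUENT_OR_SERIOUS = "frequent_or_serious"
    OCCASIONAL_OR_CLINICAL = "occasional_or_clinical"
    DOSE_CHANGE = "dose_change"
    UNLIKELY_OR_NONE = "unlikely_or_none"
    NO_INFORMATION = "no_information"


class FrequencyClass(str, enum.Enum):
    """SPC frequency classes for adverse events.

    ``ZERO`` (no AE observed at all) is distinct from ``BELOW_0_1``
    (rare/very rare, below 0.1%).
    """

    ZERO = "zero"
    BELOW_0_1 = "below_0.1"
    FROM_0_1_TO_1 = "0.1_to_1"
    FROM_1_TO_10 = "1_to_10"
    FROM_10 = "10_plus"


class RoundingMode(str, enum.Enum):
    NONE = "none"
    HALF_UP_INTEGER = "half_up_integer"


class TherapeuticContext(BaseModel):
    """Drug/indication pair plus the aim and severity-category annotations."""

    model_config = ConfigDict(frozen=True)

    drug_name: str
    atc_code: Optional[str] = None
    indication: str
    icd10_code: Optional[str] = None
    therapeutic_aim: TherapeuticAim
    disease_category: DiseaseCategory
    established_therapies: list[str] = Field(default_factory=list)

    @field_validator("established_therapies")
    @classmethod
    def _no_duplicate_therapies(cls, v: list[str]) -> list[str]:
        if len(set(v)) != len(v):
            raise ValueError("established_therapies contains duplicate entries")
        return v


class JadadItems(BaseModel):
    """The five items of the Jadad trial-quality instrument."""

    model_config = ConfigDict(frozen=True)

    randomization_mentioned: bool
    randomization_appropriate: ItemQuality = ItemQuality.NOT_DESCRIBED
    blinding_mentioned: bool
    blinding_appropriate: ItemQuality = ItemQuality.NOT_DESCRIBED
    withdrawals_described: bool

    @model_validator(mode="after")
    def _coupling(self) -> "JadadItems":
        # A method that is not mentioned cannot be judged (in)appropriate.
        if not self.randomization_mentioned and self.randomization_appropriate != ItemQuality.NOT_DESCRIBED:
            raise ValueError(
                "randomization_appropriate must be 'not_described' when "
                "randomization is not mentioned"
            )
        if not self.blinding_mentioned and self.blinding_appropriate != ItemQuality.NOT_DESCRIBED:
            raise ValueError(
                "blinding_appropriate must be 'not_described' when "
                "blinding is not mentioned"
            )
        return self


class TrialRecord(BaseModel):
    """One RCT: comparator design, outcome level, direction of the result,
    methodological quality and (optionally) the strength of effect."""

    model_config = ConfigDict(frozen=True)

    trial_id: str
    comparator_kind: ComparatorKind
    outcome_level: OutcomeLevel
    result: TrialResult
    jadad: Union[JadadItems, int]
    duration_years: Optional[float] = Field(default=None, gt=0)
    nnt: Optional[float] = Field(default=None, ge=1)
    arr: Optional[float] = Field(default=None, gt=0, le=1)
    duplicate_protocol_key: Optional[str] = None
    exclusion_note: Optional[str] = None
    nnt_provenance: Optional[str] = None

    @field_validator("jadad")
    @classmethod
    def _jadad_range(cls, v: Union[JadadItems, int]) -> Union[JadadItems, int]:
        if isinstance(v, int) and not 0 <= v <= 5:
            raise ValueError("precomputed Jadad score must lie in 0..5")
        return v

    @model_validator(mode="after")
    def _nnt_arr_consistent(self) -> "TrialRecord":
        # NNT and ARR are reciprocals; a 5% relative tolerance absorbs
        # rounding in the source publications.
        if self.nnt is not None and self.arr is not None:
            if abs(self.nnt - 1.0 / self.arr) / self.nnt > 0.05:
                raise ValueError(
                    f"nnt={self.nnt} and arr={self.arr} are inconsistent: "
                    f"1/arr={1.0 / self.arr:.3g} deviates by more than 5%"
                )
        return self

    @property
    def effective_nnt(self) -> Optional[float]:
        """NNT as given, or derived from ARR when only ARR was recorded."""
        if self.nnt is not None:
            return self.nnt
        if self.arr is not None:
            return 1.0 / self.arr
        return None


class ArmRiskProfile(BaseModel):
    """Worst single-AE frequency per CTCAE severity group for one arm.

    Each frequency is the HIGHEST occurrence of any single adverse event
    within its severity group, given either as a percent in [0, 100] or as
    a named SPC frequency class.  A value of exactly 0 means no AE of that
    group was observed and scores differently from "below 0.1%".
    """

    model_config = ConfigDict(frozen=True)

    arm_label: str
    grade_4_5_freq: Union[FrequencyClass, float]
    grade_3_freq: Union[FrequencyClass, float]
    grade_1_2_freq: Union[FrequencyClass, float]
    interaction_class: InteractionClass

    @field_validator("grade_4_5_freq", "grade_3_freq", "grade_1_2_freq")
    @classmethod
    def _percent_range(cls, v: Union[FrequencyClass, float]) -> Union[FrequencyClass, float]:
        if isinstance(v, float) and not 0.0 <= v <= 100.0:
            raise ValueError("AE frequency percent must lie in [0, 100]")
        return v


class ScoringOptions(BaseModel):
    model_config = ConfigDict(frozen=True)

    rounding: RoundingMode = RoundingMode.NONE
    yellow_half_width: float = Field(default=2.0, ge=0)


class AssessmentDossier(BaseModel):
    """Everything EVITA needs to rate one drug-indication pair.

    The drug and comparator risk profiles are expected to describe the same
    evidence base as the efficiency trials (trial AE tables, or the SPC when
    trial reporting is insufficient); this is the dossier author's
    responsibility and is not machine-checked.
    """

    schema_version: int = SCHEMA_VERSION
    context: TherapeuticContext
    trials: list[TrialRecord] = Field(default_factory=list)
    drug_risk: ArmRiskProfile
    comparator_risk: ArmRiskProfile
    options: ScoringOptions = Field(default_factory=ScoringOptions)

    @field_validator("schema_version")
    @classmethod
    def _known_schema(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v}; this build reads version {SCHEMA_VERSION}")
        return v

    @model_validator(mode="after")
    def _unique_trial_ids(self) -> "AssessmentDossier":
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("trial_id values must be unique within a dossier")
        return self
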