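"""Jadad scoring, trial inclusion/exclusion rules and setting classification."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evita import (
    ComparatorKind,
    ItemQuality,
    JadadItems,
    OutcomeLevel,
    SettingValue,
    TherapeuticContext,
    TrialRecord,
    TrialResult,
    classify_trial_setting,
    compute_jadad,
    evaluate,
    filter_trials,
    generate_synthetic_dossier,
)

# Independent oracle for the Jadad instrument, hand-coded item by item:
# one point for mentioning randomization/blinding, one more if the method
# is appropriate, one deducted if inappropriate, one point for describing
# withdrawals.
_RAND_OR_BLIND = {
    (True, ItemQuality.APPROPRIATE): 2,
    (True, ItemQuality.NOT_DESCRIBED): 1,
    (True, ItemQuality.INAPPROPRIATE): 0,
    (False, ItemQuality.NOT_DESCRIBED): 0,
}


def _valid_item_combos():
    for (rm, ra), (bm, ba), w in itertools.product(
        _RAND_OR_BLIND, _RAND_OR_BLIND, (False, True)
    ):
        yield rm, ra, bm, ba, w


class TestJadad:
    def test_exhaustive_against_item_table(self):
        combos = list(_valid_item_combos())
        assert len(combos) == 32  # 4 randomization x 4 blinding x 2 withdrawals
        for rm, ra, bm, ba, w in combos:
            expected = _RAND_OR_BLIND[(rm, ra)] + _RAND_OR_BLIND[(bm, ba)] + int(w)
            items = JadadItems(
                randomization_mentioned=rm,
                randomization_appropriate=ra,
                blinding_mentioned=bm,
                blinding_appropriate=ba,
                withdrawals_described=w,
            )
            assert compute_jadad(items) == max(expected, 0)

    def test_extremes_and_mixed(self):
        best = JadadItems(
            randomization_mentioned=True,
            randomization_appropriate="appropriate",
            blinding_mentioned=True,
            blinding_appropriate="appropriate",
            withdrawals_described=True,
        )
        assert compute_jadad(best) == 5
        worst = JadadItems(
            randomization_mentioned=False,
            blinding_mentioned=False,
            withdrawals_described=False,
        )
        assert compute_jadad(worst) == 0
        # appropriate randomization (+2), inappropriate blinding (+1-1),
        # withdrawals described (+1)
        mixed = JadadItems(
            randomization_mentioned=True,
            randomization_appropriate="appropriate",
            blinding_mentioned=True,
            blinding_appropriate="inappropriate",
            withdrawals_described=True,
        )
        assert compute_jadad(mixed) == 3


def _trial(tid, comparator="head_to_head", level="patient_relevant",
           result="superiority", jadad=5, **kw):
    return TrialRecord(
        trial_id=tid, comparator_kind=comparator, outcome_level=level,
        result=result, jadad=jadad, **kw,
    )


def _context(established=("std",)):
    return TherapeuticContext(
        drug_name="d", indication="i", therapeutic_aim="treatment",
        disease_category="I", established_therapies=list(established),
    )


class TestFilter:
    def test_low_jadad_excluded_for_quality(self):
        inc, exc = filter_trials([_trial("a", jadad=2), _trial("b", jadad=3)], _context())
        assert [t.trial_id for t in inc] == ["b"]
        assert exc == [(_trial("a", jadad=2), "quality")]

    def test_placebo_only_excluded_when_established_therapy_exists(self, dossiers):
        d = dossiers["zoledronic_pmo"]
        inc, exc = filter_trials(d.trials, d.context)
        assert inc == []
        assert {r for _, r in exc} == {"placebo despite established therapy"}

    def test_placebo_only_accepted_without_established_therapy(self):
        inc, exc = filter_trials(
            [_trial("a", comparator="placebo_only")], _context(established=())
        )
        assert [t.trial_id for t in inc] == ["a"] and exc == []

    def test_duplicate_protocol_collapses_to_one_logical_trial(self, lenalidomide):
        inc, exc = filter_trials(lenalidomide.trials, lenalidomide.context)
        assert [t.trial_id for t in inc] == ["MM-009"]
        assert [(t.trial_id, r) for t, r in exc] == [("MM-010", "duplicate protocol")]

    def test_patient_relevant_supersedes_surrogate(self, dossiers):
        d = dossiers["pioglitazone_dm2_2005"]
        inc, exc = filter_trials(d.trials, d.context)
        assert [t.trial_id for t in inc] == ["PROactive"]
        superseded = {t.trial_id for t, r in exc if r == "superseded by patient-relevant evidence"}
        assert superseded == {"PIO-ADDON-MET", "PIO-ADDON-SU"}

    def test_assessor_exclusion_note_wins(self):
        inc, exc = filter_trials(
            [_trial("a", exclusion_note="not GCP conformant")], _context()
        )
        assert inc == [] and exc[0][1] == "not GCP conformant"

    def test_empty_input(self):
        assert filter_trials([], _context()) == ([], [])

    @given(st.integers(0, 2**31 - 1), st.integers(0, 6))
    @settings(max_examples=100, deadline=None)
    def test_partition_property(self, seed, n):
        d = generate_synthetic_dossier(seed, n)
        inc, exc = filter_trials(d.trials, d.context)
        ids = sorted(t.trial_id for t in inc) + sorted(t.trial_id for t, _ in exc)
        assert sorted(ids) == sorted(t.trial_id for t in d.trials)
        assert not set(t.trial_id for t in inc) & set(t.trial_id for t, _ in exc)


class TestSetting:
    def test_lenalidomide_is_a2(self, lenalidomide):
        inc, exc = filter_trials(lenalidomide.trials, lenalidomide.context)
        assert classify_trial_setting(inc, lenalidomide.context, exc).value == SettingValue.A2

    def test_bupropion_is_b1(self, bupropion):
        inc, exc = filter_trials(bupropion.trials, bupropion.context)
        assert classify_trial_setting(inc, bupropion.context, exc).value == SettingValue.B1

    def test_empty_is_na(self):
        setting = classify_trial_setting([], _context())
        assert setting.value == SettingValue.NA and setting.included_trials == []

    @pytest.mark.parametrize(
        "level,comparator,expected",
        [
            ("patient_relevant", "head_to_head", SettingValue.A1),
            ("patient_relevant", "placebo_add_on", SettingValue.A2),
            ("surrogate", "head_to_head", SettingValue.B1),
            ("surrogate", "placebo_add_on", SettingValue.B2),
        ],
    )
    def test_four_quadrants(self, level, comparator, expected):
        trials = [_trial("a", comparator=comparator, level=level)]
        assert classify_trial_setting(trials, _context()).value == expected

    def test_head_to_head_dominates_mixed_designs(self):
        trials = [
            _trial("a", comparator="placebo_add_on", level="patient_relevant"),
            _trial("b", comparator="head_to_head", level="patient_relevant"),
        ]
        assert classify_trial_setting(trials, _context()).value == SettingValue.A1

    def test_comparison_digit_keyed_on_tier_defining_trials(self):
        # The head-to-head trial is surrogate; the tier is A, defined by the
        # placebo add-on patient-relevant trial, so the setting is A2.
        trials = [
            _trial("a", comparator="head_to_head", level="surrogate"),
            _trial("b", comparator="placebo_add_on", level="patient_relevant"),
        ]
        assert classify_trial_setting(trials, _context()).value == SettingValue.A2

    @given(st.integers(0, 2**31 - 1), st.integers(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_adding_patient_relevant_evidence_never_demotes_to_b(self, seed, n):
        d = generate_synthetic_dossier(seed, n)
        inc, exc = filter_trials(d.trials, d.context)
        before = classify_trial_setting(inc, d.context, exc).value
        extra = _trial("EXTRA", comparator="placebo_add_on", level="patient_relevant")
        inc2, exc2 = filter_trials(d.trials + [extra], d.context)
        after = classify_trial_setting(inc2, d.context, exc2).value
        if before in (SettingValue.A1, SettingValue.A2):
            assert after in (SettingValue.A1, SettingValue.A2)
        assert after != SettingValue.NA
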