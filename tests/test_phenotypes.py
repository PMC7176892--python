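"""Case definitions: boundaries, missing-data conventions, gating, grouping."""

from __future__ import annotations

import pytest

from mhqtools.instrument import DECLINED, ResponseRecord, answered
from mhqtools.phenotypes import (
    MoodGroup,
    SyndromeStatus,
    classify_alcohol,
    classify_all,
    classify_depression,
    classify_gad,
    classify_mania,
    classify_ptsd,
    classify_record,
    classify_self_harm,
    classify_unusual_experiences,
    count_self_reported_diagnoses,
    derive_bipolar,
    derive_mood_group,
)

MET = SyndromeStatus.MET
NOT_MET = SyndromeStatus.NOT_MET
UNASSESSABLE = SyndromeStatus.UNASSESSABLE


def _dep_base(**over):
    """An episode meeting every depression criterion (5 symptoms)."""
    base = {
        "DEP_SCR_MOOD": 1,
        "DEP_CORE_MOST": 1,
        "DEP_SYM_ANH": 1,
        "DEP_SYM_TIRED": 1,
        "DEP_SYM_SLEEP": 1,
        "DEP_SYM_WORTH": 1,
        "DEP_SYM_APPETITE": 0,
        "DEP_SYM_CONC": 0,
        "DEP_SYM_DEATH": 0,
        "DEP_DUR_WEEKS": 2,
        "DEP_IMPAIR": 1,
        "DEP_EPISODES": 1,
    }
    base.update(over)
    return base


class TestDepression:
    def test_full_criteria_met_single_episode(self, make_record, rules):
        res = classify_depression(make_record(_dep_base()), rules)
        assert res.status is MET
        assert res.detail["symptom_count"] == 5
        assert res.detail["episode_count"] == 1

    def test_four_symptoms_not_met(self, make_record, rules):
        res = classify_depression(
            make_record(_dep_base(DEP_SYM_WORTH=0)), rules
        )
        assert res.status is NOT_MET
        assert res.detail["symptom_count"] == 4

    def test_negative_screens_not_met_ignoring_skipped_detail(self, make_record, rules):
        res = classify_depression(
            make_record({"DEP_SCR_MOOD": 0, "DEP_SCR_ANH": 0}), rules
        )
        assert res.status is NOT_MET

    def test_one_week_duration_not_met(self, make_record, rules):
        res = classify_depression(make_record(_dep_base(DEP_DUR_WEEKS=1)), rules)
        assert res.status is NOT_MET

    def test_no_impairment_not_met(self, make_record, rules):
        res = classify_depression(make_record(_dep_base(DEP_IMPAIR=0)), rules)
        assert res.status is NOT_MET

    def test_core_not_most_of_day_not_met(self, make_record, rules):
        res = classify_depression(make_record(_dep_base(DEP_CORE_MOST=0)), rules)
        assert res.status is NOT_MET

    def test_declined_screen_is_unassessable(self, make_record, rules):
        res = classify_depression(make_record({"DEP_SCR_MOOD": "declined"}), rules)
        assert res.status is UNASSESSABLE

    def test_known_failure_decides_despite_other_missing_items(self, make_record, rules):
        # impairment known absent decides not_met even with duration missing
        values = _dep_base(DEP_IMPAIR=0)
        del values["DEP_DUR_WEEKS"]
        res = classify_depression(make_record(values), rules)
        assert res.status is NOT_MET

    def test_missing_required_duration_is_unassessable(self, make_record, rules):
        values = _dep_base()
        del values["DEP_DUR_WEEKS"]
        res = classify_depression(make_record(values), rules)
        assert res.status is UNASSESSABLE

    def test_anhedonia_screen_route_counts_as_core(self, make_record, rules):
        values = _dep_base(DEP_SCR_MOOD=0)
        values["DEP_SCR_ANH"] = 1
        values["DEP_SYM_ANH"] = 0  # anhedonia already endorsed at the screen
        res = classify_depression(make_record(values), rules)
        # symptoms: anhedonia, tired, sleep, worth = 4 (mood screen negative)
        assert res.detail["symptom_count"] == 4
        assert res.status is NOT_MET


class TestManiaBoundaries:
    def _mania(self, **over):
        base = {
            "MAN_SCR_ELATED": 1,
            "MAN_SYM_ACTIVE": 1,
            "MAN_SYM_TALKATIVE": 1,
            "MAN_SYM_SLEEP": 1,
            "MAN_SYM_CONFIDENT": 0,
            "MAN_SYM_THOUGHTS": 0,
            "MAN_SYM_DISTRACT": 0,
            "MAN_DUR_DAYS": 14,
        }
        base.update(over)
        return base

    def test_two_weeks_met(self, make_record, rules):
        assert classify_mania(make_record(self._mania()), rules).status is MET

    def test_three_days_not_met(self, make_record, rules):
        assert (
            classify_mania(make_record(self._mania(MAN_DUR_DAYS=3)), rules).status
            is NOT_MET
        )

    def test_exactly_one_week_met(self, make_record, rules):
        assert (
            classify_mania(make_record(self._mania(MAN_DUR_DAYS=7)), rules).status
            is MET
        )

    def test_no_core_endorsement_not_met(self, make_record, rules):
        rec = make_record({"MAN_SCR_ELATED": 0, "MAN_SCR_IRRIT": 0})
        assert classify_mania(rec, rules).status is NOT_MET

    def test_irritable_only_needs_four_symptoms(self, make_record, rules):
        three = self._mania(MAN_SCR_ELATED=0, MAN_SCR_IRRIT=1)
        assert classify_mania(make_record(three), rules).status is NOT_MET
        four = dict(three, MAN_SYM_CONFIDENT=1)
        assert classify_mania(make_record(four), rules).status is MET

    def test_missing_duration_with_core_endorsed_unassessable(self, make_record, rules):
        values = self._mania()
        del values["MAN_DUR_DAYS"]
        assert classify_mania(make_record(values), rules).status is UNASSESSABLE


class TestGad:
    def _gad(self, **over):
        base = {
            "GAD_SCR": 1,
            "GAD_DUR_MONTHS": 12,
            "GAD_EXCESS": 1,
            "GAD_CONTROL": 1,
            "GAD_SYM_RESTLESS": 1,
            "GAD_SYM_TIRED": 1,
            "GAD_SYM_CONC": 1,
            "GAD_SYM_IRRITABLE": 0,
            "GAD_SYM_TENSION": 0,
            "GAD_SYM_SLEEP": 0,
        }
        base.update(over)
        return base

    def test_twelve_months_with_three_symptoms_met(self, make_record, rules):
        assert classify_gad(make_record(self._gad()), rules).status is MET

    def test_three_months_not_met(self, make_record, rules):
        rec = make_record(self._gad(GAD_DUR_MONTHS=3))
        assert classify_gad(rec, rules).status is NOT_MET

    def test_screen_negative_not_met(self, make_record, rules):
        assert classify_gad(make_record({"GAD_SCR": 0}), rules).status is NOT_MET

    def test_two_somatic_symptoms_not_met(self, make_record, rules):
        rec = make_record(self._gad(GAD_SYM_CONC=0))
        assert classify_gad(rec, rules).status is NOT_MET


class TestAuditBoundaries:
    @staticmethod
    def _audit(values):
        return {f"AUDIT_{i + 1}": v for i, v in enumerate(values)}

    def test_all_zero_scores_zero_not_met(self, make_record, rules):
        res = classify_alcohol(make_record(self._audit([1] + [0] * 9)), rules)
        assert res.detail["audit_score"] == 1
        assert res.status is NOT_MET

    def test_sum_eight_met(self, make_record, rules):
        res = classify_alcohol(make_record(self._audit([4, 4] + [0] * 8)), rules)
        assert res.detail["audit_score"] == 8
        assert res.status is MET

    def test_sum_seven_not_met(self, make_record, rules):
        res = classify_alcohol(make_record(self._audit([4, 3] + [0] * 8)), rules)
        assert res.detail["audit_score"] == 7
        assert res.status is NOT_MET

    def test_declined_item_is_unassessable_without_proration(self, make_record, rules):
        values = self._audit([4, 4] + [0] * 8)
        values["AUDIT_10"] = "declined"
        res = classify_alcohol(make_record(values), rules)
        assert res.status is UNASSESSABLE
        assert res.detail["audit_score"] is None

    def test_never_drinker_skip_scores_zero_for_skipped_items(self, make_record, rules):
        res = classify_alcohol(
            make_record({"AUDIT_1": 0, "AUDIT_9": 4, "AUDIT_10": 4}), rules
        )
        assert res.detail["audit_score"] == 8
        assert res.status is MET

    def test_score_bounds(self, make_record, rules):
        res = classify_alcohol(
            make_record(self._audit([4] * 8 + [4, 4])), rules
        )
        assert res.detail["audit_score"] == 40


class TestPclBoundaries:
    @staticmethod
    def _pcl(values):
        return {f"PCL_{i + 1}": v for i, v in enumerate(values)}

    def test_floor_score_six_not_met(self, make_record, rules):
        res = classify_ptsd(make_record(self._pcl([1] * 6)), rules)
        assert res.detail["pcl_score"] == 6
        assert res.status is NOT_MET

    def test_ceiling_score_thirty_met(self, make_record, rules):
        res = classify_ptsd(make_record(self._pcl([5] * 6)), rules)
        assert res.detail["pcl_score"] == 30
        assert res.status is MET

    def test_score_exactly_at_cutoff_met(self, make_record, rules):
        values = [3, 3, 2, 2, 2, 2]
        assert sum(values) == rules.ptsd.cutoff
        assert classify_ptsd(make_record(self._pcl(values)), rules).status is MET

    def test_one_below_cutoff_not_met(self, make_record, rules):
        values = [3, 2, 2, 2, 2, 2]
        assert sum(values) == rules.ptsd.cutoff - 1
        assert classify_ptsd(make_record(self._pcl(values)), rules).status is NOT_MET

    def test_missing_item_unassessable(self, make_record, rules):
        assert (
            classify_ptsd(make_record(self._pcl([5] * 5)), rules).status
            is UNASSESSABLE
        )


class TestScreensAndSelfReport:
    def test_single_hallucination_endorsement_met(self, make_record, rules):
        rec = make_record(
            {"PSY_VISION": 1, "PSY_VOICE": 0, "PSY_CONSPIRACY": 0, "PSY_SIGNS": 0}
        )
        assert classify_unusual_experiences(rec, rules).status is MET

    def test_endorsement_dominates_missing_items(self, make_record, rules):
        rec = make_record({"PSY_VISION": 1, "PSY_VOICE": "declined"})
        assert classify_unusual_experiences(rec, rules).status is MET

    def test_all_no_not_met_and_all_declined_unassessable(self, make_record, rules):
        allno = make_record(
            {"PSY_VISION": 0, "PSY_VOICE": 0, "PSY_CONSPIRACY": 0, "PSY_SIGNS": 0}
        )
        assert classify_unusual_experiences(allno, rules).status is NOT_MET
        alldec = make_record({k: "declined" for k in
                              ("PSY_VISION", "PSY_VOICE", "PSY_CONSPIRACY", "PSY_SIGNS")})
        assert classify_unusual_experiences(alldec, rules).status is UNASSESSABLE

    @pytest.mark.parametrize(
        "value,expected",
        [(1, MET), (0, NOT_MET), ("declined", UNASSESSABLE)],
    )
    def test_self_harm_irrespective_of_intent(self, make_record, rules, value, expected):
        assert classify_self_harm(make_record({"SH_EVER": value}), rules).status is expected

    def test_diagnosis_count(self, make_record, rules, spec):
        rec = make_record({"DX_TICKS": frozenset({1, 2})})
        n, labels, ok = count_self_reported_diagnoses(rec, rules, spec)
        assert n == 2 and labels == {"Depression", "Anxiety or nerves"} and ok

    def test_diagnosis_none_ticked_and_declined(self, make_record, rules, spec):
        rec = make_record({"DX_TICKS": frozenset({0})})
        assert count_self_reported_diagnoses(rec, rules, spec) == (0, frozenset(), True)
        rec = make_record({"DX_TICKS": "declined"})
        assert count_self_reported_diagnoses(rec, rules, spec) == (0, frozenset(), False)

    def test_all_categories_ticked_counts_roster_size(self, make_record, rules, spec):
        codes = frozenset(spec.item("DX_TICKS").coding) - {0}
        rec = make_record({"DX_TICKS": codes})
        n, _, _ = count_self_reported_diagnoses(rec, rules, spec)
        assert n == len(codes)


class TestBipolarGatingAndMoodGroups:
    @staticmethod
    def _res(status, **detail):
        from mhqtools.phenotypes import SyndromeResult

        return SyndromeResult(status, detail)

    @pytest.mark.parametrize(
        "dep,man,expected",
        [
            (MET, MET, MET),
            (NOT_MET, MET, NOT_MET),  # mania without depression is never bipolar
            (MET, NOT_MET, NOT_MET),
            (NOT_MET, NOT_MET, NOT_MET),
            (MET, UNASSESSABLE, UNASSESSABLE),
            (UNASSESSABLE, NOT_MET, NOT_MET),
        ],
    )
    def test_bipolar_gating(self, dep, man, expected):
        assert derive_bipolar(self._res(dep), self._res(man)).status is expected

    def test_recurrent_depression_plus_mania_is_bipolar_group(
        self, make_record, rules, spec
    ):
        values = _dep_base(DEP_EPISODES=3)
        values.update(
            {
                "MAN_SCR_ELATED": 1,
                "MAN_SYM_ACTIVE": 1,
                "MAN_SYM_TALKATIVE": 1,
                "MAN_SYM_SLEEP": 1,
                "MAN_SYM_CONFIDENT": 0,
                "MAN_SYM_THOUGHTS": 0,
                "MAN_SYM_DISTRACT": 0,
                "MAN_DUR_DAYS": 10,
            }
        )
        rec = make_record(values)
        p = classify_record(rec, spec, rules)
        assert p.mood_group is MoodGroup.BIPOLAR_AFFECTIVE_DISORDER

    def test_screens_negative_throughout_is_no_depression(self, make_record, rules):
        dep = classify_depression(
            make_record({"DEP_SCR_MOOD": 0, "DEP_SCR_ANH": 0}), rules
        )
        bip = self._res(NOT_MET)
        assert derive_mood_group(dep, bip, rules) is MoodGroup.NO_DEPRESSION

    def test_screen_endorsed_but_criteria_unmet_is_subthreshold(self, make_record, rules):
        dep = classify_depression(make_record(_dep_base(DEP_IMPAIR=0)), rules)
        assert derive_mood_group(dep, self._res(NOT_MET), rules) is MoodGroup.SUBTHRESHOLD

    def test_episode_counts_split_single_vs_recurrent(self, make_record, rules):
        one = classify_depression(make_record(_dep_base(DEP_EPISODES=1)), rules)
        two = classify_depression(make_record(_dep_base(DEP_EPISODES=2)), rules)
        assert derive_mood_group(one, self._res(NOT_MET), rules) is MoodGroup.SINGLE_EPISODE_DEPRESSION
        assert derive_mood_group(two, self._res(NOT_MET), rules) is MoodGroup.RECURRENT_DEPRESSION

    def test_unassessable_depression_leaves_group_undefined(self, rules):
        dep = self._res(UNASSESSABLE)
        assert derive_mood_group(dep, self._res(UNASSESSABLE), rules) is None


class TestClassifyAll:
    def test_empty_cohort(self, spec, rules):
        assert classify_all([], spec, rules) == []

    def test_all_declined_record_is_all_unassessable(self, spec, rules):
        from mhqtools.instrument import apply_skip_marks

        rec = apply_skip_marks(
            spec, ResponseRecord("r", {it: DECLINED for it in spec.item_ids})
        )
        p = classify_record(rec, spec, rules)
        assert all(r.status is UNASSESSABLE for r in p.syndromes.values())
        assert p.any_syndrome is False
        assert p.any_unassessable is True

    def test_invalid_record_skipped_with_logged_reason(self, spec, rules, make_record):
        bad = ResponseRecord("bad", {"CTS_1": answered(99)})
        good = make_record({"SH_EVER": 0}, rid="good")
        messages = []
        out = classify_all([bad, good], spec, rules, skip_invalid=True, log=messages.append)
        assert [p.respondent_id for p in out] == ["good"]
        assert any("bad" in m for m in messages)
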