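"""Tabulation: cross-tabs, prevalence tables, stratified characteristics,
external comparison joins.  Toy cohorts are verified by hand enumeration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mhqtools.phenotypes import (
    MoodGroup,
    PhenotypeSet,
    SyndromeResult,
    SyndromeStatus,
    SYNDROMES,
)
from mhqtools.tabulate import (
    TABLE2_SYNDROMES,
    comorbidity_crosstab,
    characteristics_by_stratum,
    diagnosis_prevalence,
    join_external_comparison,
    mood_group_comorbidity,
    stratify_by_sex,
)

MET = SyndromeStatus.MET
NOT_MET = SyndromeStatus.NOT_MET


def make_phenotype(
    rid: str,
    met: set[str] = frozenset(),
    unassessable: set[str] = frozenset(),
    diagnoses: set[str] = frozenset(),
    dx_assessable: bool = True,
    mood_group: MoodGroup | None = MoodGroup.NO_DEPRESSION,
) -> PhenotypeSet:
    def status(name):
        if name in unassessable:
            return SyndromeStatus.UNASSESSABLE
        return MET if name in met else NOT_MET

    syndromes = {s: SyndromeResult(status(s)) for s in SYNDROMES}
    bipolar = SyndromeResult(
        MET if {"depression", "mania"} <= met else status("depression")
        if "depression" in unassessable or "mania" in unassessable
        else NOT_MET
    )
    return PhenotypeSet(
        respondent_id=rid,
        syndromes=syndromes,
        bipolar=bipolar,
        mood_group=mood_group,
        n_self_reported_diagnoses=len(diagnoses),
        diagnosis_labels=frozenset(diagnoses),
        diagnoses_assessable=dx_assessable,
        any_syndrome=bool(met),
        any_unassessable=bool(unassessable),
    )


class TestCrossTab:
    def test_four_respondent_toy_cohort_by_hand(self):
        # flags: {A,B}, {A}, {B}, {}  with A=depression, B=gad
        cohort = [
            make_phenotype("1", {"depression", "gad"}),
            make_phenotype("2", {"depression"}),
            make_phenotype("3", {"gad"}),
            make_phenotype("4", set()),
        ]
        ct = comorbidity_crosstab(cohort, labels=("depression", "gad"))
        assert ct.counts[0, 1] == 1  # A & B
        assert ct.row_totals.tolist() == [2, 2]
        assert ct.row_pct[0, 1] == 50.0
        assert ct.row_pct[1, 0] == 50.0
        assert ct.row_pct[0, 0] == 100.0

    def test_everyone_has_every_syndrome_gives_all_100(self):
        cohort = [make_phenotype(str(i), set(SYNDROMES)) for i in range(5)]
        ct = comorbidity_crosstab(cohort, labels=("depression", "gad", "self_harm"))
        assert np.all(ct.row_pct == 100.0)

    def test_empty_row_is_undefined_marker(self):
        cohort = [make_phenotype("1", {"gad"})]
        ct = comorbidity_crosstab(cohort, labels=("depression", "gad"))
        assert np.isnan(ct.row_pct[0, 0]) and np.isnan(ct.row_pct[0, 1])

    def test_unassessable_excluded_pairwise(self):
        cohort = [
            make_phenotype("1", {"depression", "gad"}),
            make_phenotype("2", {"depression"}, unassessable={"gad"}),
        ]
        ct = comorbidity_crosstab(cohort, labels=("depression", "gad"))
        # respondent 2 counts in the depression row total but not in the
        # depression x gad denominator
        assert ct.row_totals[0] == 2
        assert ct.denominators[0, 1] == 1
        assert ct.row_pct[0, 1] == 100.0

    def test_transpose_symmetry_and_conservation_on_simulated_cohort(
        self, perfect_phenotypes
    ):
        phenotypes, _ = perfect_phenotypes
        ct = comorbidity_crosstab(phenotypes)
        assert np.array_equal(ct.counts, ct.counts.T)
        mins = np.minimum.outer(ct.row_totals, ct.row_totals)
        assert np.all(ct.counts <= mins)
        for j, name in enumerate(TABLE2_SYNDROMES):
            assert ct.row_totals[j] == sum(
                p.status(name) is MET for p in phenotypes
            )


class TestDiagnosisPrevalence:
    def test_everyone_ticks_exactly_one(self):
        cohort = [make_phenotype(str(i), diagnoses={"Depression"}) for i in range(4)]
        df = diagnosis_prevalence(cohort).set_index("category")
        assert df.loc["one or more", "pct"] == 100.0
        assert df.loc["two or more", "pct"] == 0.0

    def test_no_ticks_anywhere_all_zero(self):
        cohort = [make_phenotype(str(i)) for i in range(3)]
        df = diagnosis_prevalence(cohort, categories=["Depression"])
        assert (df["count"] == 0).all()

    def test_toy_cohort_of_ten_by_hand(self):
        labels = [
            {"Depression", "Anxiety or nerves"},
            {"Depression"},
            {"Depression"},
            {"Anxiety or nerves"},
            set(),
            set(),
            {"Depression", "Anxiety or nerves", "Other"},
            set(),
            {"Other"},
            set(),
        ]
        cohort = [make_phenotype(str(i), diagnoses=s) for i, s in enumerate(labels)]
        df = diagnosis_prevalence(cohort).set_index("category")
        assert df.loc["Depression", "count"] == 4
        assert df.loc["Anxiety or nerves", "count"] == 3
        assert df.loc["Other", "count"] == 2
        assert df.loc["one or more", "count"] == 6
        assert df.loc["two or more", "count"] == 2
        assert df.loc["Depression", "pct"] == 40.0

    def test_declined_ticklists_excluded_from_denominator(self):
        cohort = [
            make_phenotype("1", diagnoses={"Depression"}),
            make_phenotype("2", dx_assessable=False),
        ]
        df = diagnosis_prevalence(cohort).set_index("category")
        assert (df["denominator"] == 1).all()


class TestCharacteristics:
    def test_stratum_of_renters_is_100_pct(self, perfect_phenotypes, perfect_risks):
        phenotypes, _ = perfect_phenotypes
        # force a deterministic check: every depression-stratum member with a
        # known tenure contributes; construct an all-renter sub-cohort
        from mhqtools.risk import RiskProfile, TriState, AgeBand

        risks = []
        for r in perfect_risks:
            risks.append(
                RiskProfile(
                    **{
                        **r.__dict__,
                        "renter": True,
                    }
                )
            )
        st = characteristics_by_stratum(phenotypes, risks, strata=("depression",))
        assert st.percentages.loc["renter", "depression"] == 100.0

    def test_empty_stratum_cells_undefined(self):
        cohort = [make_phenotype("1", set())]
        from mhqtools.risk import AgeBand, RiskProfile, TriState

        risks = [
            RiskProfile(
                respondent_id="1",
                childhood_adversity=TriState.NOT_MET,
                adult_adversity=TriState.NOT_MET,
                trauma_exposure=TriState.NOT_MET,
                loneliness=TriState.NOT_MET,
                social_isolation=TriState.NOT_MET,
                ever_smoked=TriState.NOT_MET,
                ever_cannabis=TriState.NOT_MET,
                physical_activity_met=TriState.MET,
                longstanding_illness=TriState.NOT_MET,
                townsend_quintile=1,
                renter=False,
                degree_holder=True,
                age_band=AgeBand.MID,
                sex="female",
                neuroticism_score=2,
            )
        ]
        st = characteristics_by_stratum(cohort, risks, strata=("depression",))
        assert st.stratum_n["depression"] == 0
        assert st.percentages["depression"].isna().all()

    def test_adversity_higher_in_depression_stratum(
        self, perfect_phenotypes, perfect_risks
    ):
        """The configured adversity->depression offsets must surface in the
        characteristics table."""
        phenotypes, _ = perfect_phenotypes
        st = characteristics_by_stratum(
            phenotypes, perfect_risks, strata=("depression", "none_of_the_above")
        )
        assert (
            st.percentages.loc["childhood_adversity", "depression"]
            > st.percentages.loc["childhood_adversity", "none_of_the_above"]
        )
        assert (
            st.percentages.loc["adult_adversity", "depression"]
            > st.percentages.loc["adult_adversity", "none_of_the_above"]
        )

    def test_mismatched_lengths_rejected(self, perfect_phenotypes, perfect_risks):
        phenotypes, _ = perfect_phenotypes
        with pytest.raises(ValueError):
            characteristics_by_stratum(phenotypes[:5], perfect_risks[:4])


class TestSexStratification:
    def test_alcohol_higher_in_men_depression_higher_in_women(
        self, perfect_phenotypes, perfect_risks
    ):
        phenotypes, _ = perfect_phenotypes
        st = stratify_by_sex(phenotypes, perfect_risks)
        assert (
            st.percentages.loc["alcohol_hazardous", "male"]
            > st.percentages.loc["alcohol_hazardous", "female"]
        )
        assert (
            st.percentages.loc["depression", "female"]
            > st.percentages.loc["depression", "male"]
        )

    def test_single_sex_cohort_leaves_other_column_empty(self):
        cohort = [make_phenotype("1", {"gad"})]
        from mhqtools.risk import AgeBand, RiskProfile, TriState

        risks = [
            RiskProfile(
                respondent_id="1",
                childhood_adversity=TriState.NOT_MET,
                adult_adversity=TriState.NOT_MET,
                trauma_exposure=TriState.NOT_MET,
                loneliness=TriState.NOT_MET,
                social_isolation=TriState.NOT_MET,
                ever_smoked=TriState.NOT_MET,
                ever_cannabis=TriState.NOT_MET,
                physical_activity_met=TriState.MET,
                longstanding_illness=TriState.NOT_MET,
                townsend_quintile=1,
                renter=False,
                degree_holder=True,
                age_band=AgeBand.MID,
                sex="female",
                neuroticism_score=2,
            )
        ]
        st = stratify_by_sex(cohort, risks)
        assert st.stratum_n["male"] == 0
        assert st.percentages["male"].isna().all()


class TestMoodGroupTables:
    def test_comorbidity_gradient_no_depression_to_recurrent(self, perfect_phenotypes):
        phenotypes, _ = perfect_phenotypes
        df = mood_group_comorbidity(phenotypes).set_index("mood_group")
        assert (
            df.loc["recurrent_depression", "pct"] > df.loc["no_depression", "pct"]
        )


class TestExternalJoin:
    def test_identical_label_sets_full_join(self):
        internal = pd.DataFrame({"category": ["a", "b"], "pct": [1.0, 2.0]})
        external = pd.DataFrame({"category": ["a", "b"], "pct": [1.5, 2.5]})
        joined, mismatches = join_external_comparison(internal, external)
        assert len(joined) == 2
        assert mismatches == {"internal_only": [], "external_only": []}

    def test_external_lacking_category_is_reported(self):
        internal = pd.DataFrame({"category": ["a", "addiction"], "pct": [1.0, 2.0]})
        external = pd.DataFrame({"category": ["a"], "pct": [1.5]})
        joined, mismatches = join_external_comparison(internal, external)
        assert mismatches["internal_only"] == ["addiction"]
        assert len(joined) == 2  # nothing silently dropped

    def test_empty_external_table_is_passthrough_with_full_mismatch(self):
        internal = pd.DataFrame({"category": ["a", "b"], "pct": [1.0, 2.0]})
        external = pd.DataFrame({"category": [], "pct": []})
        joined, mismatches = join_external_comparison(internal, external)
        assert mismatches["internal_only"] == ["a", "b"]
        assert set(joined["category"]) == {"a", "b"}
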