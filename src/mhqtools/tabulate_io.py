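"""Round-trip readers for phenotype and risk-profile tables.

Let the tabulation stage run standalone on files produced earlier (or by
another tool emitting the same layout)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .phenotypes import MoodGroup, PhenotypeSet, SyndromeResult, SyndromeStatus, SYNDROMES
from .risk import AgeBand, RiskProfile, TriState

__all__ = ["read_phenotypes_table", "read_risks_table"]


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return int(float(v))


def read_phenotypes_table(path: str | Path, sep: str = "\t") -> list[PhenotypeSet]:
    df = pd.read_csv(path, sep=sep, comment="#", keep_default_na=False, na_values=[])
    out: list[PhenotypeSet] = []
    for row in df.to_dict("records"):
        syndromes = {}
        for name in SYNDROMES:
            detail: dict = {}
            if name == "depression":
                detail["episode_count"] = _opt_int(row.get("episode_count"))
                detail["symptom_count"] = _opt_int(row.get("depression_symptom_count"))
            elif name == "alcohol_hazardous":
                detail["audit_score"] = _opt_int(row.get("audit_score"))
            elif name == "ptsd_current":
                detail["pcl_score"] = _opt_int(row.get("pcl_score"))
            syndromes[name] = SyndromeResult(SyndromeStatus(row[name]), detail)
        labels = frozenset(
            s for s in str(row.get("diagnosis_labels", "")).split("|") if s
        )
        mood = row.get("mood_group", "")
        out.append(
            PhenotypeSet(
                respondent_id=str(row["respondent_id"]),
                syndromes=syndromes,
                bipolar=SyndromeResult(SyndromeStatus(row["bipolar"])),
                mood_group=MoodGroup(mood) if mood else None,
                n_self_reported_diagnoses=int(row["n_self_reported_diagnoses"]),
                diagnosis_labels=labels,
                diagnoses_assessable=bool(int(row["diagnoses_assessable"])),
                any_syndrome=bool(int(row["any_syndrome"])),
                any_unassessable=bool(int(row["any_unassessable"])),
            )
        )
    return out


def read_risks_table(path: str | Path, sep: str = "\t") -> list[RiskProfile]:
    df = pd.read_csv(path, sep=sep, comment="#", keep_default_na=False, na_values=[])
    out: list[RiskProfile] = []
    for row in df.to_dict("records"):
        renter = row.get("renter", "")
        degree = row.get("degree_holder", "")
        band = row.get("age_band", "")
        out.append(
            RiskProfile(
                respondent_id=str(row["respondent_id"]),
                childhood_adversity=TriState(row["childhood_adversity"]),
                adult_adversity=TriState(row["adult_adversity"]),
                trauma_exposure=TriState(row["trauma_exposure"]),
                loneliness=TriState(row["loneliness"]),
                social_isolation=TriState(row["social_isolation"]),
                ever_smoked=TriState(row["ever_smoked"]),
                ever_cannabis=TriState(row["ever_cannabis"]),
                physical_activity_met=TriState(row["physical_activity_met"]),
                longstanding_illness=TriState(row["longstanding_illness"]),
                townsend_quintile=_opt_int(row.get("townsend_quintile")),
                renter=None if renter == "" else bool(int(renter)),
                degree_holder=None if degree == "" else bool(int(degree)),
                age_band=AgeBand(band) if band else None,
                sex=str(row["sex"]) or None,
                neuroticism_score=_opt_int(row.get("neuroticism_score")),
            )
        )
    return out
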