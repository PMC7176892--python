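"""Descriptive surfaces: comorbidity cross-tabs, diagnosis prevalence,
characteristics by stratum, sex stratification, external comparison joins.

Denominator policy (always explicit, never hidden): cross-tabs are pairwise
complete-case — a cell's denominator is the count of respondents with the
row syndrome met and the column syndrome assessable; characteristics tables
are per-cell complete-case with the excluded N recoverable from the reported
denominators.  Percentages are rendered to one decimal, and counts are always
emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .phenotypes import (
    ANY_SYNDROME_COMPONENTS,
    MoodGroup,
    PhenotypeSet,
    SyndromeStatus,
)
from .risk import AgeBand, RiskProfile, TriState

__all__ = [
    "CrossTab",
    "StratTable",
    "TABLE2_SYNDROMES",
    "TABLE3_STRATA",
    "comorbidity_crosstab",
    "diagnosis_prevalence",
    "characteristics_by_stratum",
    "mood_group_comorbidity",
    "stratify_by_sex",
    "join_external_comparison",
]

#: Row/column roster of the comorbidity table: the seven operationally
#: defined syndromes plus the gated bipolar flag.
TABLE2_SYNDROMES = (
    "depression",
    "mania",
    "gad",
    "unusual_experiences",
    "self_harm",
    "alcohol_hazardous",
    "ptsd_current",
    "bipolar",
)

#: Strata of the characteristics table; "none_of_the_above" means criteria
#: not met for depression, GAD, unusual experiences or addiction.
TABLE3_STRATA = (
    "depression",
    "bipolar",
    "gad",
    "unusual_experiences",
    "addiction",
    "none_of_the_above",
)

_NONE_STRATUM_COMPONENTS = ("depression", "gad", "unusual_experiences", "addiction")


@dataclass
class CrossTab:
    """Row-conditional comorbidity table with explicit pairwise denominators."""

    labels: tuple[str, ...]
    counts: np.ndarray  # pair met-met counts (symmetric)
    denominators: np.ndarray  # row met & column assessable
    row_totals: np.ndarray  # row met counts (own-column assessable)

    @property
    def row_pct(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.denominators > 0, 100.0 * self.counts / self.denominators, np.nan
            )

    def to_frame(self, kind: str = "pct") -> pd.DataFrame:
        data = {"pct": np.round(self.row_pct, 1), "counts": self.counts,
                "denominators": self.denominators}[kind]
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))


@dataclass
class StratTable:
    """Per-stratum percentages with explicit per-cell denominators."""

    percentages: pd.DataFrame  # characteristics x strata
    numerators: pd.DataFrame
    denominators: pd.DataFrame
    stratum_n: pd.Series  # respondents per stratum

    def to_frame(self) -> pd.DataFrame:
        return self.percentages.round(1)


def _status_matrix(
    phenotypes: Sequence[PhenotypeSet], labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(met, assessable) boolean matrices, respondents x labels."""
    met = np.zeros((len(phenotypes), len(labels)), dtype=bool)
    ok = np.zeros_like(met)
    for i, p in enumerate(phenotypes):
        for j, name in enumerate(labels):
            st = p.status(name)
            ok[i, j] = st is not SyndromeStatus.UNASSESSABLE
            met[i, j] = st is SyndromeStatus.MET
    return met, ok


def comorbidity_crosstab(
    phenotypes: Sequence[PhenotypeSet], labels: Sequence[str] = TABLE2_SYNDROMES
) -> CrossTab:
    """Pair counts and row-conditional percentages: the (i, j) percentage is
    the share of respondents with row syndrome i who also meet column
    syndrome j, among those assessable for both."""
    met, ok = _status_matrix(phenotypes, labels)
    both_ok_met = (met & ok).astype(np.int64)
    counts = both_ok_met.T @ both_ok_met
    denominators = both_ok_met.T @ ok.astype(np.int64)
    return CrossTab(
        labels=tuple(labels),
        counts=counts,
        denominators=denominators,
        row_totals=np.diag(counts).copy(),
    )


def diagnosis_prevalence(
    phenotypes: Sequence[PhenotypeSet], categories: Sequence[str] | None = None
) -> pd.DataFrame:
    """Self-reported professional-diagnosis counts and percentages, with
    cumulative "one or more" and "two or more" rows, over respondents whose
    tick-list was assessable."""
    assessable = [p for p in phenotypes if p.diagnoses_assessable]
    n = len(assessable)
    if categories is None:
        categories = sorted({lab for p in assessable for lab in p.diagnosis_labels})
    rows = []
    for cat in categories:
        count = sum(1 for p in assessable if cat in p.diagnosis_labels)
        rows.append({"category": cat, "count": count})
    for label, k in (("one or more", 1), ("two or more", 2)):
        count = sum(1 for p in assessable if p.n_self_reported_diagnoses >= k)
        rows.append({"category": label, "count": count})
    df = pd.DataFrame(rows)
    df["denominator"] = n
    df["pct"] = (100.0 * df["count"] / n).round(1) if n else np.nan
    return df


# characteristic accessors over (phenotype, risk) pairs -> True/False/None
_CHARACTERISTICS: dict[str, Callable[[PhenotypeSet, RiskProfile], bool | None]] = {
    "female": lambda p, r: None if r.sex is None else r.sex == "female",
    "aged_65_plus": lambda p, r: None if r.age_band is None else r.age_band is AgeBand.OLDER,
    "degree": lambda p, r: r.degree_holder,
    "townsend_most_deprived_quintile": lambda p, r: (
        None if r.townsend_quintile is None else r.townsend_quintile == 5
    ),
    "renter": lambda p, r: r.renter,
    "longstanding_illness": lambda p, r: _tri(r.longstanding_illness),
    "high_neuroticism": lambda p, r: (
        None if r.neuroticism_score is None else r.neuroticism_score >= 7
    ),
    "childhood_adversity": lambda p, r: _tri(r.childhood_adversity),
    "adult_adversity": lambda p, r: _tri(r.adult_adversity),
    "trauma_exposure": lambda p, r: _tri(r.trauma_exposure),
    "loneliness": lambda p, r: _tri(r.loneliness),
    "social_isolation": lambda p, r: _tri(r.social_isolation),
    "ever_smoked": lambda p, r: _tri(r.ever_smoked),
    "ever_cannabis": lambda p, r: _tri(r.ever_cannabis),
    "physical_activity_met": lambda p, r: _tri(r.physical_activity_met),
}


def _tri(v: TriState) -> bool | None:
    if v is TriState.MET:
        return True
    if v is TriState.NOT_MET:
        return False
    return None


def _stratum_members(
    phenotypes: Sequence[PhenotypeSet], strata: Sequence[str]
) -> dict[str, list[int]]:
    members: dict[str, list[int]] = {s: [] for s in strata}
    for i, p in enumerate(phenotypes):
        for s in strata:
            if s == "none_of_the_above":
                if all(
                    p.status(c) is SyndromeStatus.NOT_MET
                    for c in _NONE_STRATUM_COMPONENTS
                ):
                    members[s].append(i)
            elif s in {g.value for g in MoodGroup}:
                if p.mood_group is not None and p.mood_group.value == s:
                    members[s].append(i)
            elif p.status(s) is SyndromeStatus.MET:
                members[s].append(i)
    return members


def characteristics_by_stratum(
    phenotypes: Sequence[PhenotypeSet],
    risks: Sequence[RiskProfile],
    strata: Sequence[str] = TABLE3_STRATA,
) -> StratTable:
    """Characteristics by lifetime-syndrome status (or mood group when the
    strata are the five mood-group labels).  Respondents may appear in more
    than one syndrome stratum; every cell uses its own complete-case
    denominator."""
    if len(phenotypes) != len(risks):
        raise ValueError("phenotypes and risks must be parallel")
    members = _stratum_members(phenotypes, strata)
    chars = list(_CHARACTERISTICS)
    num = pd.DataFrame(0, index=chars, columns=list(strata), dtype=int)
    den = pd.DataFrame(0, index=chars, columns=list(strata), dtype=int)
    for s, idxs in members.items():
        for c in chars:
            fn = _CHARACTERISTICS[c]
            vals = [fn(phenotypes[i], risks[i]) for i in idxs]
            den.loc[c, s] = sum(1 for v in vals if v is not None)
            num.loc[c, s] = sum(1 for v in vals if v is True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * num / den.replace(0, np.nan)
    stratum_n = pd.Series({s: len(i) for s, i in members.items()})
    return StratTable(percentages=pct, numerators=num, denominators=den, stratum_n=stratum_n)


def characteristics_by_mood_group(
    phenotypes: Sequence[PhenotypeSet], risks: Sequence[RiskProfile]
) -> StratTable:
    return characteristics_by_stratum(
        phenotypes, risks, strata=[g.value for g in MoodGroup]
    )


def mood_group_comorbidity(phenotypes: Sequence[PhenotypeSet]) -> pd.DataFrame:
    """Share of each mood group meeting at least one non-mood syndrome
    (GAD, unusual experiences, self-harm, alcohol, PTSD)."""
    others = [s for s in ANY_SYNDROME_COMPONENTS if s not in ("depression", "mania")]
    rows = []
    for group in MoodGroup:
        idxs = [p for p in phenotypes if p.mood_group is group]
        n = len(idxs)
        count = sum(
            1 for p in idxs if any(p.status(s) is SyndromeStatus.MET for s in others)
        )
        rows.append(
            {
                "mood_group": group.value,
                "n": n,
                "any_other_syndrome": count,
                "pct": round(100.0 * count / n, 1) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def stratify_by_sex(
    phenotypes: Sequence[PhenotypeSet], risks: Sequence[RiskProfile]
) -> StratTable:
    """Syndrome percentages within women and men (assessable denominators)."""
    if len(phenotypes) != len(risks):
        raise ValueError("phenotypes and risks must be parallel")
    labels = list(TABLE2_SYNDROMES) + ["any_syndrome"]
    sexes = ("female", "male")
    num = pd.DataFrame(0, index=labels, columns=list(sexes), dtype=int)
    den = pd.DataFrame(0, index=labels, columns=list(sexes), dtype=int)
    n_by_sex = {s: 0 for s in sexes}
    for p, r in zip(phenotypes, risks):
        if r.sex not in sexes:
            continue
        n_by_sex[r.sex] += 1
        for name in TABLE2_SYNDROMES:
            st = p.status(name)
            if st is not SyndromeStatus.UNASSESSABLE:
                den.loc[name, r.sex] += 1
                if st is SyndromeStatus.MET:
                    num.loc[name, r.sex] += 1
        den.loc["any_syndrome", r.sex] += 1
        if p.any_syndrome:
            num.loc["any_syndrome", r.sex] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * num / den.replace(0, np.nan)
    return StratTable(
        percentages=pct,
        numerators=num,
        denominators=den,
        stratum_n=pd.Series(n_by_sex),
    )


def join_external_comparison(
    internal: pd.DataFrame,
    external: pd.DataFrame,
    on: str = "category",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Label-matched side-by-side join of an internal prevalence table with a
    user-supplied external one.  Unmatched categories on either side are
    listed in the mismatch report, never silently dropped."""
    for name, df in (("internal", internal), ("external", external)):
        if on not in df.columns:
            raise ValueError(f"{name} table lacks join column {on!r}")
    joined = internal.merge(
        external, on=on, how="outer", suffixes=("_internal", "_external"), sort=True
    )
    internal_labels = set(internal[on])
    external_labels = set(external[on])
    mismatches = {
        "internal_only": sorted(internal_labels - external_labels),
        "external_only": sorted(external_labels - internal_labels),
    }
    return joined, mismatches
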