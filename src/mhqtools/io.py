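"""Delimited-text I/O: response tables, data dictionary, truth and result tables.

Responses travel as delimited text (tab by default) in either a *wide*
layout (one row per respondent, one column per item) or a *long* layout
(``respondent_id, item_id, value``).  Sentinels: ``-818`` = prefer not to
answer, ``-121`` = do not know (folded into the declined status on load).
Empty wide cells are rule-skipped where the instrument's skip rules exclude
the item given the parsed answers, and absent otherwise, so records
round-trip without a dedicated skip sentinel.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .instrument import (
    ABSENT,
    DECLINED,
    DECLINED_CODE,
    UNKNOWN_CODE,
    Answer,
    InstrumentSpec,
    ResponseKind,
    ResponseRecord,
    Status,
    answered,
    apply_skip_marks,
)
from .phenotypes import PhenotypeSet
from .risk import RiskProfile

__all__ = [
    "write_responses_wide",
    "read_responses_wide",
    "read_responses_long",
    "data_dictionary",
    "write_data_dictionary",
    "phenotypes_frame",
    "write_phenotypes",
    "risks_frame",
    "write_risks",
]

_MULTI_SEP = "|"


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def _format_cell(item_kind: ResponseKind, ans: Answer) -> str:
    if ans.status is Status.ANSWERED:
        if item_kind is ResponseKind.MULTI_CHOICE:
            return _MULTI_SEP.join(str(c) for c in sorted(ans.value))
        return str(ans.value)
    if ans.status is Status.DECLINED:
        return str(DECLINED_CODE)
    return ""  # rule_skipped and absent both render empty


def _parse_cell(item_kind: ResponseKind, cell: str) -> Answer | None:
    """None means empty (absent-or-skipped, resolved later)."""
    cell = cell.strip()
    if cell == "":
        return None
    if item_kind is ResponseKind.MULTI_CHOICE and _MULTI_SEP in cell:
        return answered(frozenset(int(c) for c in cell.split(_MULTI_SEP)))
    value = int(float(cell))
    if value in (DECLINED_CODE, UNKNOWN_CODE):
        return DECLINED
    if item_kind is ResponseKind.MULTI_CHOICE:
        return answered(frozenset({value}))
    return answered(value)


def write_responses_wide(
    records: Iterable[ResponseRecord],
    spec: InstrumentSpec,
    path: str | Path,
    sep: str | None = None,
) -> None:
    sep = _sep_for(path, sep)
    item_ids = spec.item_ids
    kinds = {it.item_id: it.kind for it in spec.items}
    with open(path, "w") as fh:
        fh.write(f"# instrument_version={spec.version}\n")
        fh.write(sep.join(["respondent_id", *item_ids]) + "\n")
        for rec in records:
            cells = [
                _format_cell(kinds[i], rec.answers.get(i, ABSENT)) for i in item_ids
            ]
            fh.write(sep.join([rec.respondent_id, *cells]) + "\n")


def _finalise_record(spec: InstrumentSpec, record: ResponseRecord) -> ResponseRecord:
    """Resolve empty cells into rule_skipped vs absent via the skip engine."""
    return apply_skip_marks(spec, record)


def read_responses_wide(
    path: str | Path, spec: InstrumentSpec, sep: str | None = None
) -> list[ResponseRecord]:
    sep = _sep_for(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", keep_default_na=False)
    if "respondent_id" not in df.columns:
        raise ValueError(f"{path}: wide layout requires a 'respondent_id' column")
    item_cols = [c for c in df.columns if c != "respondent_id"]
    unknown = [c for c in item_cols if c not in spec]
    if unknown:
        raise ValueError(f"{path}: columns not in instrument: {unknown[:5]}")
    kinds = {it.item_id: it.kind for it in spec.items}
    records = []
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        answers: dict[str, Answer] = {}
        for item_id in item_cols:
            ans = _parse_cell(kinds[item_id], rowd[item_id])
            if ans is not None:
                answers[item_id] = ans
        records.append(
            _finalise_record(spec, ResponseRecord(str(rowd["respondent_id"]), answers))
        )
    return records


def read_responses_long(
    path: str | Path, spec: InstrumentSpec, sep: str | None = None
) -> list[ResponseRecord]:
    sep = _sep_for(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", keep_default_na=False)
    required = {"respondent_id", "item_id", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: long layout requires columns {sorted(required)}")
    kinds = {it.item_id: it.kind for it in spec.items}
    by_resp: dict[str, dict[str, Answer]] = {}
    for row in df.itertuples(index=False):
        item_id = str(row.item_id)
        if item_id not in kinds:
            raise ValueError(f"{path}: unknown item_id {item_id!r}")
        ans = _parse_cell(kinds[item_id], str(row.value))
        if ans is not None:
            by_resp.setdefault(str(row.respondent_id), {})[item_id] = ans
    return [
        _finalise_record(spec, ResponseRecord(rid, answers))
        for rid, answers in by_resp.items()
    ]


# ---------------------------------------------------------------------------
# data dictionary
# ---------------------------------------------------------------------------

def data_dictionary(spec: InstrumentSpec) -> pd.DataFrame:
    """One row per (item, code), plus the reserved sentinels per item."""
    rows = []
    for it in spec.items:
        base = {
            "item_id": it.item_id,
            "section": it.section,
            "kind": it.kind.value,
            "unit": it.unit or "",
        }
        if it.coding is not None:
            for code, label in sorted(it.coding.items()):
                rows.append({**base, "code": code, "label": label})
        else:
            lo, hi = it.valid_range
            rows.append({**base, "code": "", "label": f"integer {lo}..{hi}"})
        rows.append({**base, "code": DECLINED_CODE, "label": "Prefer not to answer"})
        rows.append({**base, "code": UNKNOWN_CODE, "label": "Do not know"})
    return pd.DataFrame(rows)


def write_data_dictionary(spec: InstrumentSpec, path: str | Path, sep: str | None = None) -> None:
    data_dictionary(spec).to_csv(path, sep=_sep_for(path, sep), index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def phenotypes_frame(phenotypes: Sequence[PhenotypeSet]) -> pd.DataFrame:
    rows = []
    for p in phenotypes:
        row: dict = {"respondent_id": p.respondent_id}
        for name, res in p.syndromes.items():
            row[name] = res.status.value
        row["bipolar"] = p.bipolar.status.value
        row["mood_group"] = p.mood_group.value if p.mood_group is not None else ""
        dep = p.syndromes["depression"].detail
        row["depression_symptom_count"] = dep.get("symptom_count")
        row["episode_count"] = dep.get("episode_count")
        row["audit_score"] = p.syndromes["alcohol_hazardous"].detail.get("audit_score")
        row["pcl_score"] = p.syndromes["ptsd_current"].detail.get("pcl_score")
        row["n_self_reported_diagnoses"] = p.n_self_reported_diagnoses
        row["diagnosis_labels"] = _MULTI_SEP.join(sorted(p.diagnosis_labels))
        row["diagnoses_assessable"] = int(p.diagnoses_assessable)
        row["any_syndrome"] = int(p.any_syndrome)
        row["any_unassessable"] = int(p.any_unassessable)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_stamped(df: pd.DataFrame, path: str | Path, sep: str | None, header: str) -> None:
    sep = _sep_for(path, sep)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep=sep, index=False)


def write_phenotypes(
    phenotypes: Sequence[PhenotypeSet],
    path: str | Path,
    instrument_version: str,
    ruleset_version: str,
    sep: str | None = None,
) -> None:
    _write_stamped(
        phenotypes_frame(phenotypes),
        path,
        sep,
        f"# instrument_version={instrument_version}\n# ruleset_version={ruleset_version}\n",
    )


def risks_frame(risks: Sequence[RiskProfile]) -> pd.DataFrame:
    rows = []
    for r in risks:
        rows.append(
            {
                "respondent_id": r.respondent_id,
                "childhood_adversity": r.childhood_adversity.value,
                "adult_adversity": r.adult_adversity.value,
                "trauma_exposure": r.trauma_exposure.value,
                "loneliness": r.loneliness.value,
                "social_isolation": r.social_isolation.value,
                "ever_smoked": r.ever_smoked.value,
                "ever_cannabis": r.ever_cannabis.value,
                "physical_activity_met": r.physical_activity_met.value,
                "longstanding_illness": r.longstanding_illness.value,
                "townsend_quintile": r.townsend_quintile,
                "renter": "" if r.renter is None else int(r.renter),
                "degree_holder": "" if r.degree_holder is None else int(r.degree_holder),
                "age_band": r.age_band.value if r.age_band is not None else "",
                "sex": r.sex or "",
                "neuroticism_score": r.neuroticism_score,
            }
        )
    return pd.DataFrame(rows)


def write_risks(
    risks: Sequence[RiskProfile],
    path: str | Path,
    instrument_version: str,
    ruleset_version: str,
    sep: str | None = None,
) -> None:
    _write_stamped(
        risks_frame(risks),
        path,
        sep,
        f"# instrument_version={instrument_version}\n# ruleset_version={ruleset_version}\n",
    )
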