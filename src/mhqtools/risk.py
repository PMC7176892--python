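"""Risk-factor and covariate derivations: exposure screens and demographic
recodes used by the characteristics tables.

Tri-state screens follow the same missing-data convention as the syndrome
classifiers (declined/absent required items -> unassessable under
three-valued logic).  Demographic recodes are total over the documented
codings and fail loudly on unknown codes.

The adult-adversity screen and the loneliness screen share the
confiding-relationship item: both read the single source item, so there is
no double entry of that exposure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

from .instrument import InstrumentSpec, ResponseRecord, Status
from .phenotypes import TriBool, _any_endorsed, _code, _yes, kor
from .ruleset import Ruleset

__all__ = [
    "TriState",
    "AgeBand",
    "RiskProfile",
    "RecodeError",
    "screen_childhood_trauma",
    "screen_adult_adversity",
    "screen_trauma_exposure",
    "screen_loneliness",
    "screen_social_isolation",
    "derive_risk_profile",
    "derive_all_risks",
]


class RecodeError(ValueError):
    """An input field carried a code outside its documented coding."""


class TriState(str, enum.Enum):
    MET = "met"
    NOT_MET = "not_met"
    UNASSESSABLE = "unassessable"


class AgeBand(str, enum.Enum):
    MID = "45-64"
    OLDER = "65+"


def _tri(verdict: TriBool) -> TriState:
    if verdict is True:
        return TriState.MET
    if verdict is False:
        return TriState.NOT_MET
    return TriState.UNASSESSABLE


@dataclass
class RiskProfile:
    respondent_id: str
    childhood_adversity: TriState
    adult_adversity: TriState
    trauma_exposure: TriState
    loneliness: TriState
    social_isolation: TriState
    ever_smoked: TriState
    ever_cannabis: TriState
    physical_activity_met: TriState
    longstanding_illness: TriState
    townsend_quintile: int | None
    renter: bool | None
    degree_holder: bool | None
    age_band: AgeBand | None
    sex: str | None
    neuroticism_score: int | None


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def screen_childhood_trauma(record: ResponseRecord, rules: Ruleset) -> TriState:
    """Possible childhood abuse or neglect: any screener item endorsed at or
    above its configured frequency threshold."""
    parts: list[TriBool] = []
    for item, threshold in rules.childhood_trauma.item_thresholds.items():
        v = _code(record, item)
        parts.append(None if v is None else v >= threshold)
    return _tri(kor(*parts))


def screen_adult_adversity(record: ResponseRecord, rules: Ruleset) -> TriState:
    """Adult adversity: lack of a confiding relationship, abusive
    relationships, or serious money problems."""
    return _tri(_any_endorsed(record, rules.adult_adversity.items))


def screen_trauma_exposure(record: ResponseRecord, rules: Ruleset) -> TriState:
    """One or more of six situations known to trigger trauma-related
    disorders."""
    return _tri(_any_endorsed(record, rules.trauma_triggers.items))


def screen_loneliness(record: ResponseRecord, rules: Ruleset) -> TriState:
    """Often lonely, or lacking a confidant (shared source item with the
    adult-adversity screen)."""
    r = rules.loneliness
    return _tri(kor(_yes(record, r.lonely_item), _yes(record, r.confide_item)))


def screen_social_isolation(record: ResponseRecord, rules: Ruleset) -> TriState:
    """Composite isolation screen: living alone, infrequent contact with
    family/friends, no regular group activity; met at/above the configured
    component count."""
    r = rules.social_isolation
    alone = _yes(record, r.live_alone_item)
    contact = _code(record, r.contact_item)
    infrequent = None if contact is None else contact >= r.infrequent_contact_min_code
    group = _yes(record, r.group_item)
    no_group = None if group is None else not group
    parts = [alone, infrequent, no_group]
    n_true = sum(1 for p in parts if p is True)
    n_unknown = sum(1 for p in parts if p is None)
    if n_true >= r.min_components:
        return TriState.MET
    if n_true + n_unknown < r.min_components:
        return TriState.NOT_MET
    return TriState.UNASSESSABLE


# ---------------------------------------------------------------------------
# demographic recodes
# ---------------------------------------------------------------------------

_RENTER_CODES = {3, 4}  # social and private rent; other tenures excluded


def _answered_code(record: ResponseRecord, item: str, spec: InstrumentSpec) -> int | None:
    st = record.status(item)
    if st is not Status.ANSWERED:
        return None
    value = record.value(item)
    if not spec.item(item).is_legal_value(value):
        raise RecodeError(f"field {item!r}: unknown code {value!r}")
    return value


def _tri_item(record: ResponseRecord, item: str, spec: InstrumentSpec) -> TriState:
    v = _answered_code(record, item, spec)
    return _tri(None if v is None else v == 1)


def derive_risk_profile(
    record: ResponseRecord, spec: InstrumentSpec, rules: Ruleset
) -> RiskProfile:
    """All Table-3-style exposure flags and demographic recodes for one
    respondent."""
    age = _answered_code(record, "AGE", spec)
    sex_code = _answered_code(record, "SEX", spec)
    tenure = _answered_code(record, "TENURE", spec)
    return RiskProfile(
        respondent_id=record.respondent_id,
        childhood_adversity=screen_childhood_trauma(record, rules),
        adult_adversity=screen_adult_adversity(record, rules),
        trauma_exposure=screen_trauma_exposure(record, rules),
        loneliness=screen_loneliness(record, rules),
        social_isolation=screen_social_isolation(record, rules),
        ever_smoked=_tri_item(record, "SMOKED_EVER", spec),
        ever_cannabis=_tri_item(record, "CANNABIS_EVER", spec),
        physical_activity_met=_tri_item(record, "PHYS_ACT", spec),
        longstanding_illness=_tri_item(record, "LONGILL", spec),
        townsend_quintile=_answered_code(record, "TOWNSEND_Q", spec),
        renter=None if tenure is None else tenure in _RENTER_CODES,
        degree_holder=(
            None
            if (v := _answered_code(record, "EDU_DEGREE", spec)) is None
            else v == 1
        ),
        age_band=None if age is None else (AgeBand.OLDER if age >= 65 else AgeBand.MID),
        sex=None if sex_code is None else ("male" if sex_code == 1 else "female"),
        neuroticism_score=_answered_code(record, "NEUROTICISM", spec),
    )


def derive_all_risks(
    records: Iterable[ResponseRecord], spec: InstrumentSpec, rules: Ruleset
) -> list[RiskProfile]:
    return [derive_risk_profile(r, spec, rules) for r in records]
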