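"""Operational case definitions: deterministic tri-state syndrome classifiers.

Each classifier maps a :class:`~mhqtools.instrument.ResponseRecord` to
``met`` / ``not_met`` / ``unassessable``.  The missing-data convention is:

* an item removed by a skip rule contributes "criterion not endorsed"
  (the respondent screened out of that block);
* a criterion-required item that was presented but declined or absent makes
  the criterion *unknown*; the classification is ``unassessable`` only when
  the overall verdict cannot be decided without it (three-valued logic, so a
  record that already fails a known criterion is still ``not_met``).

Exceptions required by the summed scales: the AUDIT and PCL sums are not
prorated, so any declined/absent bound item makes those two classifications
``unassessable`` outright.

Derived outputs: the bipolar flag is *gated* on depression (likely bipolar
affective disorder is only assigned with a history of depression, where
screening has acceptable positive predictive value), and the five-level
mood-disorder grouping applies the precedence bipolar > recurrent depression
> single-episode depression > subthreshold symptoms > no depression.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .instrument import InstrumentSpec, ResponseRecord, Status
from .ruleset import Ruleset

__all__ = [
    "SyndromeStatus",
    "MoodGroup",
    "SyndromeResult",
    "PhenotypeSet",
    "SYNDROMES",
    "ANY_SYNDROME_COMPONENTS",
    "classify_depression",
    "classify_mania",
    "classify_gad",
    "classify_alcohol",
    "classify_ptsd",
    "classify_unusual_experiences",
    "classify_self_harm",
    "classify_addiction",
    "count_self_reported_diagnoses",
    "derive_bipolar",
    "derive_mood_group",
    "classify_record",
    "classify_all",
]


class SyndromeStatus(str, enum.Enum):
    MET = "met"
    NOT_MET = "not_met"
    UNASSESSABLE = "unassessable"


class MoodGroup(str, enum.Enum):
    NO_DEPRESSION = "no_depression"
    SUBTHRESHOLD = "subthreshold"
    SINGLE_EPISODE_DEPRESSION = "single_episode_depression"
    RECURRENT_DEPRESSION = "recurrent_depression"
    BIPOLAR_AFFECTIVE_DISORDER = "bipolar_affective_disorder"


#: Syndromes with latent ground truth in the synthetic cohort.
SYNDROMES = (
    "depression",
    "mania",
    "gad",
    "unusual_experiences",
    "self_harm",
    "alcohol_hazardous",
    "ptsd_current",
    "addiction",
)

#: Components of the any-syndrome flag (addiction is reported separately).
ANY_SYNDROME_COMPONENTS = (
    "depression",
    "mania",
    "gad",
    "unusual_experiences",
    "self_harm",
    "alcohol_hazardous",
    "ptsd_current",
)


@dataclass
class SyndromeResult:
    status: SyndromeStatus
    detail: dict = field(default_factory=dict)

    @property
    def met(self) -> bool:
        return self.status is SyndromeStatus.MET


@dataclass
class PhenotypeSet:
    """Per-respondent classification bundle."""

    respondent_id: str
    syndromes: dict[str, SyndromeResult]
    bipolar: SyndromeResult
    mood_group: MoodGroup | None
    n_self_reported_diagnoses: int
    diagnosis_labels: frozenset[str]
    diagnoses_assessable: bool
    any_syndrome: bool
    any_unassessable: bool

    def status(self, syndrome: str) -> SyndromeStatus:
        if syndrome == "bipolar":
            return self.bipolar.status
        return self.syndromes[syndrome].status


# ---------------------------------------------------------------------------
# three-valued (Kleene) logic helpers; None encodes "unknown"
# ---------------------------------------------------------------------------

TriBool = bool | None


def kand(*vals: TriBool) -> TriBool:
    if any(v is False for v in vals):
        return False
    if any(v is None for v in vals):
        return None
    return True


def kor(*vals: TriBool) -> TriBool:
    if any(v is True for v in vals):
        return True
    if any(v is None for v in vals):
        return None
    return False


def _yes(record: ResponseRecord, item_id: str) -> TriBool:
    """Endorsement of a yes/no item.  Rule-skipped counts as not endorsed,
    unless the skip was caused by a declined gate (then unknown)."""
    st = record.status(item_id)
    if st is Status.ANSWERED:
        return record.value(item_id) == 1
    if st is Status.RULE_SKIPPED and item_id not in record.decline_skipped:
        return False
    return None


def _code(record: ResponseRecord, item_id: str, skipped_value: int | None = 0) -> int | None:
    """Numeric value of an item; rule-skipped maps to *skipped_value* (None
    when the skip came from a declined gate)."""
    st = record.status(item_id)
    if st is Status.ANSWERED:
        return record.value(item_id)
    if st is Status.RULE_SKIPPED and item_id not in record.decline_skipped:
        return skipped_value
    return None


def _at_least(vals: Sequence[TriBool], k: int) -> TriBool:
    """Does the count of True values reach *k*, under unknowns?"""
    n_true = sum(1 for v in vals if v is True)
    n_unknown = sum(1 for v in vals if v is None)
    if n_true >= k:
        return True
    if n_true + n_unknown < k:
        return False
    return None


def _ge(value: int | None, threshold: int) -> TriBool:
    return None if value is None else value >= threshold


def _result(verdict: TriBool, detail: dict | None = None) -> SyndromeResult:
    if verdict is True:
        status = SyndromeStatus.MET
    elif verdict is False:
        status = SyndromeStatus.NOT_MET
    else:
        status = SyndromeStatus.UNASSESSABLE
    return SyndromeResult(status, detail or {})


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def classify_depression(record: ResponseRecord, rules: Ruleset) -> SyndromeResult:
    """Lifetime major depressive episode (CIDI-SF, DSM-IV operationalisation).

    Met iff at least one core feature (depressed mood or anhedonia) was
    present most of the day nearly every day for at least two weeks, the
    total symptom count (core features plus associated symptoms) reaches
    five, and the episode caused impairment.  ``detail['episode_count']``
    distinguishes single from recurrent illness.
    """
    r = rules.depression
    mood = _yes(record, r.screen_mood_item)
    anh_screen = _yes(record, r.screen_anhedonia_item)
    screen_any = kor(mood, anh_screen)
    core_most = _yes(record, r.core_most_item)
    anhedonia = kor(anh_screen, _yes(record, r.anhedonia_symptom_item))
    symptoms: list[TriBool] = [mood, anhedonia]
    symptoms += [_yes(record, it) for it in r.other_symptom_items]
    count_ok = _at_least(symptoms, r.min_symptoms)
    duration = _code(record, r.duration_item)
    dur_ok = _ge(duration, r.min_duration_weeks)
    impair = _yes(record, r.impairment_item) if r.require_impairment else True
    met = kand(screen_any, core_most, count_ok, dur_ok, impair)
    episodes = _code(record, r.episodes_item)
    detail = {
        "symptom_count": sum(1 for v in symptoms if v is True),
        "duration_weeks": duration,
        "episode_count": episodes,
        "screen_endorsed": screen_any,
    }
    return _result(met, detail)


def classify_mania(record: ResponseRecord, rules: Ruleset) -> SyndromeResult:
    """Lifetime hypomania/mania: elated or irritable period with the required
    associated-symptom count, lasting at least one week."""
    r = rules.mania
    elated = _yes(record, r.screen_elated_item)
    irritable = _yes(record, r.screen_irritable_item)
    symptoms = [_yes(record, it) for it in r.symptom_items]
    duration = _code(record, r.duration_item)
    dur_ok = _ge(duration, r.min_duration_days)
    met = kand(
        dur_ok,
        kor(
            kand(elated, _at_least(symptoms, r.min_symptoms_elated)),
            kand(irritable, _at_least(symptoms, r.min_symptoms_irritable_only)),
        ),
    )
    detail = {
        "symptom_count": sum(1 for v in symptoms if v is True),
        "duration_days": duration,
    }
    return _result(met, detail)


def classify_gad(record: ResponseRecord, rules: Ruleset) -> SyndromeResult:
    """Lifetime generalised anxiety disorder (CIDI-SF, DSM-IV): excessive,
    hard-to-control worry for at least six months with associated symptoms."""
    r = rules.gad
    screen = _yes(record, r.screen_item)
    duration = _code(record, r.duration_item)
    symptoms = [_yes(record, it) for it in r.symptom_items]
    met = kand(
        screen,
        _ge(duration, r.min_duration_months),
        _yes(record, r.excessive_item),
        _yes(record, r.control_item),
        _at_least(symptoms, r.min_symptoms),
    )
    detail = {
        "symptom_count": sum(1 for v in symptoms if v is True),
        "duration_months": duration,
    }
    return _result(met, detail)


def classify_alcohol(record: ResponseRecord, rules: Ruleset) -> SyndromeResult:
    """Past-year hazardous/harmful alcohol use: AUDIT total at/above cut-off.

    No proration: any declined/absent AUDIT item makes the score, and hence
    the classification, unassessable.  Rule-skipped consumption items (never
    drinkers) score zero.
    """
    values = [_code(record, it) for it in rules.alcohol.items]
    if any(v is None for v in values):
        return _result(None, {"audit_score": None})
    score = sum(values)
    return _result(score >= rules.alcohol.cutoff, {"audit_score": score})


def classify_ptsd(record: ResponseRecord, rules: Ruleset) -> SyndromeResult:
    """Current (past-month) PTSD on the 6-item short-form checklist: item sum
    at/above the configured cut-off.  Not prorated."""
    values = [_code(record, it, skipped_value=None) for it in rules.ptsd.items]
    if any(v is None for v in values):
        return _result(None, {"pcl_score": None})
    score = sum(values)
    return _result(score >= rules.ptsd.cutoff, {"pcl_score": score})


def _any_endorsed(record: ResponseRecord, items: Iterable[str]) -> TriBool:
    return kor(*(_yes(record, it) for it in items))


def classify_unusual_experiences(record: ResponseRecord, rules: Ruleset) -> SyndromeResult:
    """Lifetime unusual (psychotic-like) experience: any item endorsed."""
    return _result(_any_endorsed(record, rules.unusual_experiences.items))


def classify_self_harm(record: ResponseRecord, rules: Ruleset) -> SyndromeResult:
    """Lifetime self-harm, irrespective of suicidal intent."""
    return _result(_yes(record, rules.self_harm.item))


def classify_addiction(record: ResponseRecord, rules: Ruleset) -> SyndromeResult:
    """Self-reported lifetime addiction/dependence (single item)."""
    return _result(_yes(record, rules.addiction.item))


def count_self_reported_diagnoses(
    record: ResponseRecord, rules: Ruleset, spec: InstrumentSpec
) -> tuple[int, frozenset[str], bool]:
    """Distinct professional-diagnosis categories ticked.

    Returns (count, labels, assessable); a declined/absent tick-list yields
    an empty set and is flagged not assessable for denominators.
    """
    r = rules.diagnoses
    st = record.status(r.item)
    if st is not Status.ANSWERED:
        return 0, frozenset(), False
    codes = record.value(r.item)
    coding = spec.item(r.item).coding
    labels = frozenset(coding[c] for c in codes if c != r.none_code)
    return len(labels), labels, True


def derive_bipolar(depression: SyndromeResult, mania: SyndromeResult) -> SyndromeResult:
    """Likely bipolar affective disorder: both lifetime depression and
    lifetime mania met (mania alone is never labelled bipolar)."""
    verdict = kand(
        None if depression.status is SyndromeStatus.UNASSESSABLE else depression.met,
        None if mania.status is SyndromeStatus.UNASSESSABLE else mania.met,
    )
    return _result(verdict)


def derive_mood_group(
    depression: SyndromeResult, bipolar: SyndromeResult, rules: Ruleset
) -> MoodGroup | None:
    """Five-level mood-disorder grouping.

    Precedence: bipolar > recurrent depression > single-episode depression >
    subthreshold (depression screen endorsed, criteria unmet) > no
    depression.  ``None`` when the depression status (or, for met
    depression, the episode count) is unassessable; such records are
    excluded from mood tables and surface in the QC report.
    """
    if depression.status is SyndromeStatus.UNASSESSABLE:
        return None
    if bipolar.status is SyndromeStatus.MET:
        return MoodGroup.BIPOLAR_AFFECTIVE_DISORDER
    if depression.status is SyndromeStatus.MET:
        episodes = depression.detail.get("episode_count")
        if episodes is None:
            return None
        if episodes >= rules.depression.recurrent_min_episodes:
            return MoodGroup.RECURRENT_DEPRESSION
        return MoodGroup.SINGLE_EPISODE_DEPRESSION
    if depression.detail.get("screen_endorsed") is True:
        return MoodGroup.SUBTHRESHOLD
    return MoodGroup.NO_DEPRESSION


_CLASSIFIERS: dict[str, Callable[[ResponseRecord, Ruleset], SyndromeResult]] = {
    "depression": classify_depression,
    "mania": classify_mania,
    "gad": classify_gad,
    "unusual_experiences": classify_unusual_experiences,
    "self_harm": classify_self_harm,
    "alcohol_hazardous": classify_alcohol,
    "ptsd_current": classify_ptsd,
    "addiction": classify_addiction,
}


def classify_record(
    record: ResponseRecord, spec: InstrumentSpec, rules: Ruleset
) -> PhenotypeSet:
    """Apply every classifier to one record."""
    syndromes = {name: fn(record, rules) for name, fn in _CLASSIFIERS.items()}
    bipolar = derive_bipolar(syndromes["depression"], syndromes["mania"])
    mood_group = derive_mood_group(syndromes["depression"], bipolar, rules)
    n_dx, labels, dx_ok = count_self_reported_diagnoses(record, rules, spec)
    any_syndrome = any(syndromes[s].met for s in ANY_SYNDROME_COMPONENTS)
    any_unassessable = any(
        syndromes[s].status is SyndromeStatus.UNASSESSABLE for s in SYNDROMES
    )
    return PhenotypeSet(
        respondent_id=record.respondent_id,
        syndromes=syndromes,
        bipolar=bipolar,
        mood_group=mood_group,
        n_self_reported_diagnoses=n_dx,
        diagnosis_labels=labels,
        diagnoses_assessable=dx_ok,
        any_syndrome=any_syndrome,
        any_unassessable=any_unassessable,
    )


def classify_all(
    records: Iterable[ResponseRecord],
    spec: InstrumentSpec,
    rules: Ruleset,
    *,
    skip_invalid: bool = False,
    log: Callable[[str], None] | None = None,
) -> list[PhenotypeSet]:
    """Classify a cohort, preserving record order.

    With ``skip_invalid``, records failing structural validation are dropped
    with a logged reason instead of being classified.
    """
    from .instrument import validate_responses

    out: list[PhenotypeSet] = []
    for record in records:
        if skip_invalid:
            violations = validate_responses(spec, record)
            if violations:
                if log is not None:
                    log(
                        f"skipping respondent {record.respondent_id}: "
                        f"{len(violations)} validation violation(s), first: "
                        f"{violations[0].message}"
                    )
                continue
        out.append(classify_record(record, spec, rules))
    return out
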