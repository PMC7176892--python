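"""Branching-questionnaire model: items, codings, skip rules and response semantics.

The instrument is an ordered list of coded items plus *skip rules*: a screening
answer can suppress presentation of downstream detail items, so respondents
only see the sections relevant to them.  This module owns the authoritative
answer to "which items should this respondent have been shown", the four-way
response status model (answered / declined / rule-skipped / absent), and
structural validation of both instruments and response records.

Skip-rule semantics
-------------------
A rule fires when its trigger item was *presented* and either (a) it was
answered with one of the rule's trigger codes, or (b) it was declined or
answered "do not know" (a respondent who declines a screening question is
conservatively skipped past the items it gates).  A rule whose trigger item
was itself removed by an earlier rule never fires.  Rules only ever point
forward in instrument order, so a single forward pass resolves presentation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "SECTIONS",
    "ResponseKind",
    "Status",
    "Answer",
    "Completion",
    "ItemDef",
    "SkipRule",
    "InstrumentSpec",
    "ResponseRecord",
    "Violation",
    "InstrumentError",
    "SchemaError",
    "ValidationError",
    "load_instrument",
    "default_instrument",
    "write_instrument",
    "resolve_presented_items",
    "apply_skip_marks",
    "validate_responses",
    "completion_status",
]

#: Recognised questionnaire sections.
SECTIONS = (
    "demographics_link",
    "wellbeing",
    "diagnoses",
    "depression",
    "mania",
    "anxiety",
    "psychotic_experiences",
    "self_harm",
    "trauma_ptsd",
    "alcohol",
    "addiction",
)

#: Reserved sentinel codes used in delimited response files.
DECLINED_CODE = -818
UNKNOWN_CODE = -121
RESERVED_CODES = frozenset({DECLINED_CODE, UNKNOWN_CODE})


class InstrumentError(ValueError):
    """Base class for instrument-related failures."""


class SchemaError(InstrumentError):
    """An instrument file does not parse against the documented schema."""


class ValidationError(InstrumentError):
    """A structurally invalid instrument (dangling or cyclic skip rules...)."""


class ResponseKind(str, enum.Enum):
    SINGLE_CHOICE = "single_choice"
    MULTI_CHOICE = "multi_choice"
    INTEGER = "integer"
    DURATION = "duration"


class Status(str, enum.Enum):
    ANSWERED = "answered"
    DECLINED = "declined"
    RULE_SKIPPED = "rule_skipped"
    ABSENT = "absent"


class Completion(str, enum.Enum):
    COMPLETE = "complete"
    PARTIAL = "partial"
    NOT_STARTED = "not_started"


@dataclass(frozen=True)
class Answer:
    """One item's response: a status, and a value iff status is ``answered``.

    Values are ``int`` codes for single-choice / integer / duration items and
    ``frozenset[int]`` for multi-choice (tick-all-that-apply) items.
    """

    status: Status
    value: object = None

    def __post_init__(self) -> None:
        if self.status is Status.ANSWERED and self.value is None:
            raise ValueError("answered status requires a value")
        if self.status is not Status.ANSWERED and self.value is not None:
            raise ValueError(f"status {self.status.value} carries no value")


DECLINED = Answer(Status.DECLINED)
RULE_SKIPPED = Answer(Status.RULE_SKIPPED)
ABSENT = Answer(Status.ABSENT)


def answered(value: object) -> Answer:
    if isinstance(value, (set, frozenset)):
        value = frozenset(int(v) for v in value)
    return Answer(Status.ANSWERED, value)


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item with its coding.

    ``coding`` maps substantive integer codes to labels for choice items; the
    reserved decline/unknown sentinels are instrument-wide and never appear in
    ``coding``.  Integer and duration items carry an inclusive ``valid_range``
    instead of a coding; duration items also carry a ``unit``.
    """

    item_id: str
    section: str
    prompt: str
    kind: ResponseKind
    coding: Mapping[int, str] | None = None
    valid_range: tuple[int, int] | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ValidationError(f"item {self.item_id}: unknown section {self.section!r}")
        if self.kind in (ResponseKind.SINGLE_CHOICE, ResponseKind.MULTI_CHOICE):
            if not self.coding:
                raise ValidationError(f"item {self.item_id}: choice item requires a coding")
            if RESERVED_CODES & set(self.coding):
                raise ValidationError(
                    f"item {self.item_id}: coding reuses a reserved decline/unknown code"
                )
        else:
            if self.valid_range is None:
                raise ValidationError(f"item {self.item_id}: numeric item requires valid_range")
            lo, hi = self.valid_range
            if lo > hi:
                raise ValidationError(f"item {self.item_id}: empty valid_range")

    def is_legal_value(self, value: object) -> bool:
        """True iff *value* is a substantive legal response for this item."""
        if self.kind is ResponseKind.SINGLE_CHOICE:
            return isinstance(value, int) and value in self.coding
        if self.kind is ResponseKind.MULTI_CHOICE:
            return (
                isinstance(value, frozenset)
                and all(isinstance(v, int) and v in self.coding for v in value)
                and len(value) > 0
            )
        lo, hi = self.valid_range
        return isinstance(value, int) and lo <= value <= hi


@dataclass(frozen=True)
class SkipRule:
    """If the trigger item's answer is in ``trigger_codes`` (or the trigger is
    declined), the listed downstream items are not presented."""

    trigger_item: str
    trigger_codes: frozenset[int]
    skipped_items: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trigger_codes", frozenset(self.trigger_codes))
        object.__setattr__(self, "skipped_items", tuple(self.skipped_items))
        if self.trigger_item in self.skipped_items:
            raise ValidationError(f"rule on {self.trigger_item}: item is its own trigger")

    def fires(self, ans: Answer) -> bool:
        if ans.status is Status.DECLINED:
            return True
        if ans.status is not Status.ANSWERED:
            return False
        value = ans.value
        if isinstance(value, frozenset):
            return bool(value & self.trigger_codes)
        return value in self.trigger_codes


@dataclass
class InstrumentSpec:
    """A versioned, ordered questionnaire with skip rules."""

    version: str
    items: list[ItemDef]
    rules: list[SkipRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {it.item_id: i for i, it in enumerate(self.items)}
        if len(self._index) != len(self.items):
            seen: set[str] = set()
            for it in self.items:
                if it.item_id in seen:
                    raise ValidationError(f"duplicate item_id {it.item_id!r}")
                seen.add(it.item_id)
        for rule in self.rules:
            if rule.trigger_item not in self._index:
                raise ValidationError(
                    f"skip rule references missing trigger item {rule.trigger_item!r}"
                )
            for target in rule.skipped_items:
                if target not in self._index:
                    raise ValidationError(
                        f"skip rule on {rule.trigger_item!r} references missing item {target!r}"
                    )
                if self._index[target] <= self._index[rule.trigger_item]:
                    raise ValidationError(
                        f"skip rule on {rule.trigger_item!r}: skipped item {target!r} "
                        "does not occur after its trigger (instrument order must be "
                        "a topological order)"
                    )
        # Rules are applied in trigger order; forward-only targets make the
        # rule graph acyclic by construction.
        self.rules = sorted(self.rules, key=lambda r: self._index[r.trigger_item])

    # -- lookups ---------------------------------------------------------
    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def item(self, item_id: str) -> ItemDef:
        return self.items[self._index[item_id]]

    def order(self, item_id: str) -> int:
        return self._index[item_id]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def section_items(self, section: str) -> list[ItemDef]:
        return [it for it in self.items if it.section == section]

    @property
    def sections(self) -> list[str]:
        seen: list[str] = []
        for it in self.items:
            if it.section not in seen:
                seen.append(it.section)
        return seen

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InstrumentSpec):
            return NotImplemented
        return (
            self.version == other.version
            and self.items == other.items
            and self.rules == other.rules
        )

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        items = []
        for it in self.items:
            d: dict = {
                "id": it.item_id,
                "section": it.section,
                "prompt": it.prompt,
                "kind": it.kind.value,
            }
            if it.coding is not None:
                d["coding"] = {int(k): v for k, v in it.coding.items()}
            if it.valid_range is not None:
                d["range"] = list(it.valid_range)
            if it.unit is not None:
                d["unit"] = it.unit
            items.append(d)
        rules = [
            {
                "trigger": r.trigger_item,
                "codes": sorted(r.trigger_codes),
                "skips": list(r.skipped_items),
            }
            for r in self.rules
        ]
        return {
            "version": self.version,
            "reserved_codes": {"declined": DECLINED_CODE, "unknown": UNKNOWN_CODE},
            "items": items,
            "rules": rules,
        }


@dataclass
class ResponseRecord:
    """One respondent's coded answers, bound to an instrument by item ids.

    ``decline_skipped`` records which rule-skipped items were excluded by a
    *declined* gate rather than a substantive screen-out answer: such items
    carry no "criterion not endorsed" information and classifiers treat them
    as unknown.  It is derived by :func:`apply_skip_marks`.
    """

    respondent_id: str
    answers: dict[str, Answer] = field(default_factory=dict)
    decline_skipped: set[str] = field(default_factory=set)

    def status(self, item_id: str) -> Status:
        ans = self.answers.get(item_id)
        return ans.status if ans is not None else Status.ABSENT

    def value(self, item_id: str) -> object:
        ans = self.answers.get(item_id)
        return ans.value if ans is not None else None


@dataclass(frozen=True)
class Violation:
    """A single response-validation failure (data, not an exception)."""

    kind: str  # illegal_code | answered_inside_skip | skipped_but_presented | missing_skip_mark | unknown_item
    item_id: str
    message: str


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def _parse_item(d: Mapping, pos: int) -> ItemDef:
    try:
        item_id = d["id"]
        section = d["section"]
        kind = ResponseKind(d["kind"])
    except KeyError as exc:
        raise SchemaError(f"item #{pos}: missing required field {exc.args[0]!r}") from None
    except ValueError:
        raise SchemaError(f"item {d.get('id', pos)!r}: unknown kind {d.get('kind')!r}") from None
    coding = d.get("coding")
    if coding is not None:
        try:
            coding = {int(k): str(v) for k, v in coding.items()}
        except (TypeError, ValueError):
            raise SchemaError(f"item {item_id!r}: field 'coding' must map int codes to labels")
    rng = d.get("range")
    if rng is not None:
        if not (isinstance(rng, (list, tuple)) and len(rng) == 2):
            raise SchemaError(f"item {item_id!r}: field 'range' must be [lo, hi]")
        rng = (int(rng[0]), int(rng[1]))
    try:
        return ItemDef(
            item_id=str(item_id),
            section=str(section),
            prompt=str(d.get("prompt", "")),
            kind=kind,
            coding=coding,
            valid_range=rng,
            unit=d.get("unit"),
        )
    except ValidationError as exc:
        raise SchemaError(str(exc)) from None


def instrument_from_dict(doc: Mapping) -> InstrumentSpec:
    if not isinstance(doc, Mapping):
        raise SchemaError("instrument file must contain a mapping at top level")
    for fieldname in ("version", "items"):
        if fieldname not in doc:
            raise SchemaError(f"missing required field {fieldname!r}")
    items = [_parse_item(d, i) for i, d in enumerate(doc["items"])]
    rules = []
    for i, rd in enumerate(doc.get("rules", [])):
        try:
            rules.append(
                SkipRule(
                    trigger_item=str(rd["trigger"]),
                    trigger_codes=frozenset(int(c) for c in rd["codes"]),
                    skipped_items=tuple(str(s) for s in rd["skips"]),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"rule #{i}: missing required field {exc.args[0]!r}") from None
    return InstrumentSpec(version=str(doc["version"]), items=items, rules=rules)


def load_instrument(path: str | Path) -> InstrumentSpec:
    """Load and validate an instrument from its YAML file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"{path}: not valid YAML: {exc}") from None
    return instrument_from_dict(doc)


def write_instrument(spec: InstrumentSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False, allow_unicode=True)


def default_instrument() -> InstrumentSpec:
    """The bundled default questionnaire skeleton (``mhq_default``)."""
    path = Path(__file__).parent / "data" / "mhq_default.yaml"
    return load_instrument(path)


# ---------------------------------------------------------------------------
# presentation semantics
# ---------------------------------------------------------------------------

def resolve_presented_items(spec: InstrumentSpec, record: ResponseRecord) -> set[str]:
    """Exactly the items a compliant respondent would be shown.

    Pure function of (spec, record): walks the instrument in order, firing
    each skip rule against the recorded answer of its (still-presented)
    trigger item and removing that rule's targets.
    """
    excluded: set[str] = set()
    for rule in spec.rules:  # sorted by trigger position
        if rule.trigger_item in excluded:
            continue
        if rule.fires(record.answers.get(rule.trigger_item, ABSENT)):
            excluded.update(rule.skipped_items)
    return {it.item_id for it in spec.items} - excluded


def apply_skip_marks(spec: InstrumentSpec, record: ResponseRecord) -> ResponseRecord:
    """Bring a record's rule-skipped marks in line with the skip engine.

    Excluded items are marked ``rule_skipped`` (discarding any stale value);
    items marked ``rule_skipped`` that are in fact presented revert to
    ``absent`` (the respondent never reached them, e.g. after censoring a
    gate).  Also derives ``decline_skipped``: the items excluded only by
    declined gates.
    """
    excluded: set[str] = set()
    by_decline: set[str] = set()
    by_answer: set[str] = set()
    for rule in spec.rules:
        if rule.trigger_item in excluded:
            continue
        ans = record.answers.get(rule.trigger_item, ABSENT)
        if ans.status is Status.DECLINED:
            excluded.update(rule.skipped_items)
            by_decline.update(rule.skipped_items)
        elif rule.fires(ans):
            excluded.update(rule.skipped_items)
            by_answer.update(rule.skipped_items)
    for item_id in spec.item_ids:
        if item_id in excluded:
            record.answers[item_id] = RULE_SKIPPED
        elif record.status(item_id) is Status.RULE_SKIPPED:
            record.answers[item_id] = ABSENT
    record.decline_skipped = by_decline - by_answer
    return record


def validate_responses(spec: InstrumentSpec, record: ResponseRecord) -> list[Violation]:
    """Structural validation of a record against its instrument.

    Empty iff (a) every substantive value is a legal code, (b) the
    rule-skipped status appears exactly on the items excluded by
    :func:`resolve_presented_items`, and (c) no answered item lies downstream
    of a triggered skip.
    """
    violations: list[Violation] = []
    for item_id in record.answers:
        if item_id not in spec:
            violations.append(
                Violation("unknown_item", item_id, f"item {item_id!r} not in instrument")
            )
    presented = resolve_presented_items(spec, record)
    for item in spec.items:
        ans = record.answers.get(item.item_id, ABSENT)
        if item.item_id in presented:
            if ans.status is Status.RULE_SKIPPED:
                violations.append(
                    Violation(
                        "skipped_but_presented",
                        item.item_id,
                        f"item {item.item_id!r} marked rule_skipped but no rule excludes it",
                    )
                )
            elif ans.status is Status.ANSWERED and not item.is_legal_value(ans.value):
                violations.append(
                    Violation(
                        "illegal_code",
                        item.item_id,
                        f"item {item.item_id!r}: illegal code {ans.value!r}",
                    )
                )
        else:
            if ans.status in (Status.ANSWERED, Status.DECLINED):
                violations.append(
                    Violation(
                        "answered_inside_skip",
                        item.item_id,
                        f"item {item.item_id!r} has a response but lies inside a "
                        "triggered skip block",
                    )
                )
            elif ans.status is Status.ABSENT:
                violations.append(
                    Violation(
                        "missing_skip_mark",
                        item.item_id,
                        f"item {item.item_id!r} is excluded by a rule but not marked "
                        "rule_skipped",
                    )
                )
    return violations


def completion_status(spec: InstrumentSpec, record: ResponseRecord) -> Completion:
    """Complete iff every presented item was answered or declined; not
    started iff nothing was answered at all."""
    if not any(a.status is Status.ANSWERED for a in record.answers.values()):
        return Completion.NOT_STARTED
    presented = resolve_presented_items(spec, record)
    for item_id in presented:
        if record.status(item_id) not in (Status.ANSWERED, Status.DECLINED):
            return Completion.PARTIAL
    return Completion.COMPLETE
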