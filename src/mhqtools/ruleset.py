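"""Versioned criteria rulesets: thresholds, required counts and item bindings.

Every numeric threshold used by the case-definition classifiers lives in a
structured-text ruleset file rather than in code, so that the operational
criteria of a deployed instrument can be transcribed exactly without touching
the classifiers.  The bundled default (``rules_default``) encodes DSM-IV
operationalisations of the named screening instruments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["Ruleset", "load_ruleset", "default_ruleset", "RulesetError"]


class RulesetError(ValueError):
    pass


@dataclass(frozen=True)
class DepressionRules:
    screen_mood_item: str
    screen_anhedonia_item: str
    core_most_item: str
    anhedonia_symptom_item: str
    other_symptom_items: tuple[str, ...]
    duration_item: str
    impairment_item: str
    episodes_item: str
    min_symptoms: int = 5
    min_duration_weeks: int = 2
    require_impairment: bool = True
    recurrent_min_episodes: int = 2


@dataclass(frozen=True)
class ManiaRules:
    screen_elated_item: str
    screen_irritable_item: str
    symptom_items: tuple[str, ...]
    duration_item: str
    min_duration_days: int = 7
    min_symptoms_elated: int = 3
    min_symptoms_irritable_only: int = 4


@dataclass(frozen=True)
class GadRules:
    screen_item: str
    duration_item: str
    excessive_item: str
    control_item: str
    symptom_items: tuple[str, ...]
    min_duration_months: int = 6
    min_symptoms: int = 3


@dataclass(frozen=True)
class SumScaleRules:
    """A summed checklist with a met-at-or-above cut-off (AUDIT, PCL)."""

    items: tuple[str, ...]
    cutoff: int


@dataclass(frozen=True)
class AnyEndorsedRules:
    """Met iff any listed yes/no item is endorsed."""

    items: tuple[str, ...]


@dataclass(frozen=True)
class SingleItemRules:
    item: str


@dataclass(frozen=True)
class DiagnosesRules:
    item: str
    none_code: int = 0


@dataclass(frozen=True)
class ChildhoodTraumaRules:
    """Met iff any screener item is endorsed at/above its frequency threshold."""

    item_thresholds: Mapping[str, int]


@dataclass(frozen=True)
class LonelinessRules:
    lonely_item: str
    confide_item: str  # shared with the adult-adversity screen (single source item)


@dataclass(frozen=True)
class SocialIsolationRules:
    live_alone_item: str
    contact_item: str
    infrequent_contact_min_code: int
    group_item: str
    min_components: int = 2


@dataclass(frozen=True)
class Ruleset:
    version: str
    depression: DepressionRules
    mania: ManiaRules
    gad: GadRules
    alcohol: SumScaleRules
    ptsd: SumScaleRules
    unusual_experiences: AnyEndorsedRules
    self_harm: SingleItemRules
    addiction: SingleItemRules
    diagnoses: DiagnosesRules
    childhood_trauma: ChildhoodTraumaRules
    adult_adversity: AnyEndorsedRules
    trauma_triggers: AnyEndorsedRules
    loneliness: LonelinessRules
    social_isolation: SocialIsolationRules
    provisional: bool = True


def _build(cls, section: str, doc: Mapping, **casts):
    if section not in doc:
        raise RulesetError(f"ruleset missing required section {section!r}")
    d = dict(doc[section])
    for key, cast in casts.items():
        if key in d:
            d[key] = cast(d[key])
    try:
        return cls(**d)
    except TypeError as exc:
        raise RulesetError(f"ruleset section {section!r}: {exc}") from None


def ruleset_from_dict(doc: Mapping) -> Ruleset:
    if not isinstance(doc, Mapping) or "version" not in doc:
        raise RulesetError("ruleset must be a mapping with a 'version' field")
    tup = tuple
    return Ruleset(
        version=str(doc["version"]),
        provisional=bool(doc.get("provisional", True)),
        depression=_build(DepressionRules, "depression", doc, other_symptom_items=tup),
        mania=_build(ManiaRules, "mania", doc, symptom_items=tup),
        gad=_build(GadRules, "gad", doc, symptom_items=tup),
        alcohol=_build(SumScaleRules, "alcohol", doc, items=tup),
        ptsd=_build(SumScaleRules, "ptsd", doc, items=tup),
        unusual_experiences=_build(AnyEndorsedRules, "unusual_experiences", doc, items=tup),
        self_harm=_build(SingleItemRules, "self_harm", doc),
        addiction=_build(SingleItemRules, "addiction", doc),
        diagnoses=_build(DiagnosesRules, "diagnoses", doc),
        childhood_trauma=_build(
            ChildhoodTraumaRules, "childhood_trauma", doc, item_thresholds=dict
        ),
        adult_adversity=_build(AnyEndorsedRules, "adult_adversity", doc, items=tup),
        trauma_triggers=_build(AnyEndorsedRules, "trauma_triggers", doc, items=tup),
        loneliness=_build(LonelinessRules, "loneliness", doc),
        social_isolation=_build(SocialIsolationRules, "social_isolation", doc),
    )


def load_ruleset(path: str | Path) -> Ruleset:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise RulesetError(f"{path}: not valid YAML: {exc}") from None
    return ruleset_from_dict(doc)


def default_ruleset() -> Ruleset:
    return load_ruleset(Path(__file__).parent / "data" / "ruleset_default.yaml")
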