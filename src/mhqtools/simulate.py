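"""Synthetic cohort generator with known latent ground truth.

Stands in for access-restricted study data: draws respondents with latent
lifetime/current syndrome states, demographic covariates, and skip-consistent
item responses.

Latent model
------------
The eight syndrome indicators follow a pairwise-tilted multivariate Bernoulli
(an Ising-style model): for state vector ``x`` the joint mass is proportional
to ``exp(sum_i a_i x_i + sum_{i<j} b_ij x_i x_j)``.  The pairwise tilts
``b_ij`` (log-odds-ratio scale) encode comorbidity; the fields ``a_i`` are
calibrated by coordinate-wise bisection so the *expected* marginals — averaged
over the covariate mixture, since covariates shift the fields — match the
configured prevalences.  With only eight nodes the 256-state distribution is
computed exactly per covariate stratum, so calibration and sampling are exact.

Emission model
--------------
Item responses are produced in two stages per scale.  First a
classification-consistency coin: with probability ``sensitivity`` a
true-positive profile yields a criteria-satisfying response pattern, and with
probability ``1 - specificity`` a true-negative does.  Second, a concrete
pattern is drawn uniformly from the enumerated set of skip-consistent
patterns whose classification matches that outcome (integer items are
enumerated over small representative value grids).  Voluntary nonresponse is
then applied: each answered item is independently declined with
``decline_rate``, and with ``partial_rate`` the respondent abandons the
questionnaire at a uniformly chosen point.  Every emitted record passes
structural validation with zero violations.

Reproducibility: one global seed; the latent draw and each respondent's
emission use independent counter-derived substreams, so records do not depend
on generation order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.stats import binom as binom_dist

from .instrument import (
    ABSENT,
    DECLINED,
    RULE_SKIPPED,
    Answer,
    InstrumentSpec,
    ResponseRecord,
    Status,
    answered,
    apply_skip_marks,
    resolve_presented_items,
)
from .phenotypes import (
    SYNDROMES,
    SyndromeStatus,
    classify_addiction,
    classify_alcohol,
    classify_depression,
    classify_gad,
    classify_mania,
    classify_ptsd,
    classify_self_harm,
    classify_unusual_experiences,
)
from .risk import TriState, screen_adult_adversity, screen_childhood_trauma, \
    screen_loneliness, screen_trauma_exposure
from .ruleset import Ruleset

__all__ = [
    "ConfigError",
    "CohortConfig",
    "LatentProfile",
    "TruthTable",
    "load_cohort_config",
    "default_cohort_config",
    "calibrate_fields",
    "sample_latent",
    "EmissionModel",
    "emit_responses",
    "generate_cohort",
]

#: Latent syndrome nodes of the pairwise joint model (depression is a single
#: node; met profiles split into single/recurrent downstream).
LATENT_NODES = (
    "depression",
    "mania",
    "gad",
    "unusual_experiences",
    "self_harm",
    "alcohol_hazardous",
    "ptsd_current",
    "addiction",
)

#: Binary covariate features that shift the latent fields (log-odds offsets).
OFFSET_FEATURES = (
    "male",
    "over65",
    "childhood_adversity",
    "adult_adversity",
    "trauma_exposure",
    "loneliness",
    "high_neuroticism",
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Fidelity:
    sensitivity: float = 1.0
    specificity: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")


@dataclass
class CohortConfig:
    """Simulation configuration; see ``data/cohort_default.yaml``."""

    n: int
    seed: int = 0
    marginal_prevalence: dict[str, float] = field(default_factory=dict)
    association: np.ndarray | None = None  # (8, 8) symmetric, zero diagonal
    recurrent_share: float = 0.6
    covariates: dict = field(default_factory=dict)
    syndrome_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    emission_fidelity: dict[str, Fidelity] = field(default_factory=dict)
    decline_rate: float = 0.0
    partial_rate: float = 0.0
    screen_engage_given_negative: dict[str, float] = field(default_factory=dict)
    diagnosis_model: dict = field(default_factory=dict)
    behaviour_model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be non-negative")
        if self.association is None:
            self.association = np.zeros((len(LATENT_NODES), len(LATENT_NODES)))
        self.association = np.asarray(self.association, dtype=float)
        if self.association.shape != (len(LATENT_NODES),) * 2:
            raise ConfigError("association matrix must be 8x8 over the latent nodes")
        if not np.allclose(self.association, self.association.T):
            raise ConfigError("association matrix must be symmetric")
        if not np.allclose(np.diag(self.association), 0.0):
            raise ConfigError("association matrix must have zero diagonal")
        for name in LATENT_NODES:
            p = self.marginal_prevalence.get(name)
            if p is None:
                raise ConfigError(f"marginal_prevalence missing syndrome {name!r}")
            if not (0.0 < p < 1.0):
                raise ConfigError(f"marginal_prevalence[{name!r}] must be in (0, 1)")
        for rate_name in ("decline_rate", "partial_rate", "recurrent_share"):
            v = getattr(self, rate_name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{rate_name} must be in [0, 1]")

    def fidelity(self, scale: str) -> Fidelity:
        return self.emission_fidelity.get(
            scale, self.emission_fidelity.get("default", Fidelity())
        )


@dataclass
class LatentProfile:
    """A synthetic respondent's ground truth."""

    respondent_id: str
    true_state: dict[str, bool]  # keys: SYNDROMES split into single/recurrent
    age_years: int
    sex: str  # female | male
    degree_holder: bool
    townsend_quintile: int
    renter: bool
    longstanding_illness: bool
    neuroticism_score: int
    childhood_adversity: bool
    adult_adversity: bool
    trauma_exposure: bool
    loneliness: bool

    @property
    def depression_any(self) -> bool:
        return self.true_state["depression_single"] or self.true_state["depression_recurrent"]

    def node_state(self, node: str) -> bool:
        if node == "depression":
            return self.depression_any
        return self.true_state[node]


@dataclass
class TruthTable:
    profiles: list[LatentProfile]

    @property
    def respondent_ids(self) -> list[str]:
        return [p.respondent_id for p in self.profiles]

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in self.profiles:
            row = {
                "respondent_id": p.respondent_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "degree_holder": int(p.degree_holder),
                "townsend_quintile": p.townsend_quintile,
                "renter": int(p.renter),
                "longstanding_illness": int(p.longstanding_illness),
                "neuroticism_score": p.neuroticism_score,
                "childhood_adversity": int(p.childhood_adversity),
                "adult_adversity": int(p.adult_adversity),
                "trauma_exposure": int(p.trauma_exposure),
                "loneliness": int(p.loneliness),
            }
            row.update({k: int(v) for k, v in p.true_state.items()})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def _association_matrix(pairs: Iterable[Sequence]) -> np.ndarray:
    B = np.zeros((len(LATENT_NODES), len(LATENT_NODES)))
    idx = {name: i for i, name in enumerate(LATENT_NODES)}
    for entry in pairs or []:
        a, b, tilt = entry
        if a not in idx or b not in idx:
            raise ConfigError(f"latent_association names unknown syndrome in {entry!r}")
        B[idx[a], idx[b]] = B[idx[b], idx[a]] = float(tilt)
    return B


def cohort_config_from_dict(doc: Mapping, n: int | None = None, seed: int | None = None) -> CohortConfig:
    if not isinstance(doc, Mapping):
        raise ConfigError("cohort config must be a mapping")
    fidelity = {}
    for key, d in (doc.get("emission_fidelity") or {}).items():
        fidelity[key] = Fidelity(float(d["sensitivity"]), float(d["specificity"]))
    return CohortConfig(
        n=int(doc["n"]) if n is None else int(n),
        seed=int(doc.get("seed", 0)) if seed is None else int(seed),
        marginal_prevalence={k: float(v) for k, v in doc["marginal_prevalence"].items()},
        association=_association_matrix(doc.get("latent_association", [])),
        recurrent_share=float(doc.get("recurrent_share", 0.6)),
        covariates=dict(doc.get("covariates", {})),
        syndrome_offsets={
            k: {s: float(x) for s, x in v.items()}
            for k, v in (doc.get("syndrome_offsets") or {}).items()
        },
        emission_fidelity=fidelity,
        decline_rate=float(doc.get("decline_rate", 0.0)),
        partial_rate=float(doc.get("partial_rate", 0.0)),
        screen_engage_given_negative={
            k: float(v)
            for k, v in (doc.get("screen_engage_given_negative") or {}).items()
        },
        diagnosis_model=dict(doc.get("diagnosis_model", {})),
        behaviour_model=dict(doc.get("behaviour_model", {})),
    )


def load_cohort_config(path: str | Path, n: int | None = None, seed: int | None = None) -> CohortConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return cohort_config_from_dict(doc, n=n, seed=seed)


def default_cohort_config(n: int | None = None, seed: int | None = None, **overrides) -> CohortConfig:
    """The bundled default study conditions, optionally with field overrides."""
    cfg = load_cohort_config(
        Path(__file__).parent / "data" / "cohort_default.yaml", n=n, seed=seed
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg


# ---------------------------------------------------------------------------
# latent sampling
# ---------------------------------------------------------------------------

_STATES = np.array(list(itertools.product((0, 1), repeat=len(LATENT_NODES))), dtype=float)


def _feature_probs(config: CohortConfig) -> dict[str, float]:
    cov = config.covariates
    neu_p = float(cov.get("neuroticism_binom_p", 0.33))
    neu_cut = int(cov.get("neuroticism_high_cut", 7))
    return {
        "male": 1.0 - float(cov.get("female_rate", 0.57)),
        "over65": float(cov.get("over65_rate", 0.53)),
        "childhood_adversity": float(cov.get("childhood_adversity_rate", 0.20)),
        "adult_adversity": float(cov.get("adult_adversity_rate", 0.25)),
        "trauma_exposure": float(cov.get("trauma_exposure_rate", 0.30)),
        "loneliness": float(cov.get("loneliness_rate", 0.18)),
        "high_neuroticism": float(binom_dist.sf(neu_cut - 1, 12, neu_p)),
    }


def _stratum_offsets(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """All covariate strata: (weights (K,), field offsets (K, 8))."""
    probs = _feature_probs(config)
    node_idx = {name: i for i, name in enumerate(LATENT_NODES)}
    feat_offsets = np.zeros((len(OFFSET_FEATURES), len(LATENT_NODES)))
    for f, feat in enumerate(OFFSET_FEATURES):
        for syndrome, shift in (config.syndrome_offsets.get(feat) or {}).items():
            if syndrome not in node_idx:
                raise ConfigError(f"syndrome_offsets[{feat!r}] names unknown syndrome {syndrome!r}")
            feat_offsets[f, node_idx[syndrome]] = shift
    combos = np.array(list(itertools.product((0, 1), repeat=len(OFFSET_FEATURES))), dtype=float)
    p = np.array([probs[f] for f in OFFSET_FEATURES])
    weights = np.prod(np.where(combos == 1, p, 1 - p), axis=1)
    offsets = combos @ feat_offsets
    return weights, offsets


def _mixture_marginals(alpha: np.ndarray, offsets: np.ndarray, weights: np.ndarray,
                       pair_term: np.ndarray) -> np.ndarray:
    """Expected marginals of the tilted joint, averaged over strata."""
    logits = _STATES @ (alpha[None, :] + offsets).T + pair_term[:, None]  # (256, K)
    logits -= logits.max(axis=0, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=0, keepdims=True)
    per_stratum = probs.T @ _STATES  # (K, 8)
    return weights @ per_stratum


def calibrate_fields(config: CohortConfig, tol: float = 1e-4, max_sweeps: int = 200) -> np.ndarray:
    """Calibrate the latent fields so expected marginals hit the configured
    prevalences (coordinate-wise bisection; exact 256-state evaluation)."""
    targets = np.array([config.marginal_prevalence[s] for s in LATENT_NODES])
    weights, offsets = _stratum_offsets(config)
    pair_term = 0.5 * np.einsum("si,ij,sj->s", _STATES, config.association, _STATES)
    alpha = np.log(targets / (1 - targets))
    lo, hi = -30.0, 30.0
    for _ in range(max_sweeps):
        for i in range(len(LATENT_NODES)):
            def f(a: float) -> float:
                trial = alpha.copy()
                trial[i] = a
                return _mixture_marginals(trial, offsets, weights, pair_term)[i] - targets[i]

            if f(lo) > 0 or f(hi) < 0:
                raise ConfigError(
                    f"infeasible calibration: marginal for {LATENT_NODES[i]!r} "
                    "unattainable under the configured tilts and offsets"
                )
            alpha[i] = brentq(f, lo, hi, xtol=1e-10)
        dev = np.abs(_mixture_marginals(alpha, offsets, weights, pair_term) - targets)
        if dev.max() < tol:
            return alpha
    raise ConfigError("field calibration did not converge")


def sample_latent(config: CohortConfig, rng: np.random.Generator) -> list[LatentProfile]:
    """Draw ``config.n`` latent profiles (ground truth, no item responses)."""
    n = config.n
    if n == 0:
        return []
    cov = config.covariates
    age_lo, age_hi = (int(v) for v in cov.get("age_range", (45, 82)))
    probs = _feature_probs(config)

    male = rng.random(n) < probs["male"]
    over65 = rng.random(n) < probs["over65"]
    age = np.where(
        over65,
        rng.integers(max(65, age_lo), age_hi + 1, size=n),
        rng.integers(age_lo, 65, size=n),
    )
    degree = rng.random(n) < float(cov.get("degree_rate", 0.45))
    townsend_probs = np.asarray(cov.get("townsend_probs", [0.2] * 5), dtype=float)
    townsend = rng.choice(np.arange(1, 6), size=n, p=townsend_probs / townsend_probs.sum())
    renter = rng.random(n) < float(cov.get("renter_rate", 0.11))
    longill = rng.random(n) < float(cov.get("longstanding_illness_rate", 0.28))
    neuroticism = rng.binomial(12, float(cov.get("neuroticism_binom_p", 0.33)), size=n)
    neu_cut = int(cov.get("neuroticism_high_cut", 7))
    cts = rng.random(n) < probs["childhood_adversity"]
    aa = rng.random(n) < probs["adult_adversity"]
    trauma = rng.random(n) < probs["trauma_exposure"]
    lonely = rng.random(n) < probs["loneliness"]

    features = np.column_stack(
        [male, over65, cts, aa, trauma, lonely, neuroticism >= neu_cut]
    ).astype(int)
    # _stratum_offsets enumerates feature combinations in the same bit order
    stratum = features @ (1 << np.arange(len(OFFSET_FEATURES) - 1, -1, -1))

    alpha = calibrate_fields(config)
    weights, offsets = _stratum_offsets(config)
    pair_term = 0.5 * np.einsum("si,ij,sj->s", _STATES, config.association, _STATES)

    states = np.zeros((n, len(LATENT_NODES)), dtype=bool)
    for s in np.unique(stratum):
        mask = stratum == s
        logits = _STATES @ (alpha + offsets[s]) + pair_term
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
        drawn = rng.choice(len(_STATES), size=int(mask.sum()), p=p)
        states[mask] = _STATES[drawn].astype(bool)

    recurrent = rng.random(n) < config.recurrent_share

    profiles: list[LatentProfile] = []
    node_idx = {name: i for i, name in enumerate(LATENT_NODES)}
    for i in range(n):
        dep = states[i, node_idx["depression"]]
        true_state = {
            "depression_single": bool(dep and not recurrent[i]),
            "depression_recurrent": bool(dep and recurrent[i]),
            "mania": bool(states[i, node_idx["mania"]]),
            "gad": bool(states[i, node_idx["gad"]]),
            "unusual_experiences": bool(states[i, node_idx["unusual_experiences"]]),
            "self_harm": bool(states[i, node_idx["self_harm"]]),
            "alcohol_hazardous": bool(states[i, node_idx["alcohol_hazardous"]]),
            "ptsd_current": bool(states[i, node_idx["ptsd_current"]]),
            "addiction": bool(states[i, node_idx["addiction"]]),
        }
        profiles.append(
            LatentProfile(
                respondent_id=f"R{i + 1:06d}",
                true_state=true_state,
                age_years=int(age[i]),
                sex="male" if male[i] else "female",
                degree_holder=bool(degree[i]),
                townsend_quintile=int(townsend[i]),
                renter=bool(renter[i]),
                longstanding_illness=bool(longill[i]),
                neuroticism_score=int(neuroticism[i]),
                childhood_adversity=bool(cts[i]),
                adult_adversity=bool(aa[i]),
                trauma_exposure=bool(trauma[i]),
                loneliness=bool(lonely[i]),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# pattern enumeration and emission
# ---------------------------------------------------------------------------

#: Value grids for enumerating integer/duration items (small representative
#: sets spanning both sides of every criterion threshold).
_EMISSION_GRIDS: dict[str, tuple[int, ...]] = {
    "DEP_DUR_WEEKS": (1, 2, 4, 26),
    "DEP_EPISODES": (1, 2, 3, 10),
    "MAN_DUR_DAYS": (1, 3, 7, 14),
    "GAD_DUR_MONTHS": (1, 3, 6, 24),
    "CTS_1": (0, 1, 2, 4),
    "CTS_2": (0, 1, 2, 4),
    "CTS_3": (0, 1, 2, 4),
    "CTS_4": (0, 1, 2, 4),
    "CTS_5": (0, 1, 2, 4),
    "PCL_1": (1, 3, 5),
    "PCL_2": (1, 3, 5),
    "PCL_3": (1, 3, 5),
    "PCL_4": (1, 3, 5),
    "PCL_5": (1, 3, 5),
    "PCL_6": (1, 3, 5),
    "AUDIT_1": (0, 2, 4),
    "AUDIT_2": (0, 2, 4),
    "AUDIT_3": (0, 2, 4),
    "AUDIT_4": (0, 2, 4),
    "AUDIT_5": (0, 2, 4),
    "AUDIT_6": (0, 2, 4),
    "AUDIT_7": (0, 2, 4),
    "AUDIT_8": (0, 2, 4),
}

_SKIP = object()  # marker for a rule-skipped item inside a pattern


def _item_grid(spec: InstrumentSpec, item_id: str) -> tuple[int, ...]:
    if item_id in _EMISSION_GRIDS:
        return _EMISSION_GRIDS[item_id]
    item = spec.item(item_id)
    if item.coding is not None:
        return tuple(sorted(item.coding))
    raise ConfigError(f"no emission grid for numeric item {item_id!r}")


def enumerate_block_patterns(
    spec: InstrumentSpec, item_ids: Sequence[str]
) -> list[dict[str, object]]:
    """All skip-consistent answer patterns over a block of items.

    Walks the items in instrument order, applying the instrument's skip rules
    within the block; integer items take values from their emission grids.
    """
    items = sorted(item_ids, key=spec.order)
    item_set = set(items)
    rules = [r for r in spec.rules if r.trigger_item in item_set]
    patterns: list[dict[str, object]] = []

    def walk(idx: int, current: dict[str, object], excluded: set[str]) -> None:
        if idx == len(items):
            patterns.append(dict(current))
            return
        item_id = items[idx]
        if item_id in excluded:
            current[item_id] = _SKIP
            walk(idx + 1, current, excluded)
            del current[item_id]
            return
        for value in _item_grid(spec, item_id):
            current[item_id] = value
            new_excluded = excluded
            for rule in rules:
                if rule.trigger_item == item_id and value in rule.trigger_codes:
                    if new_excluded is excluded:
                        new_excluded = set(excluded)
                    new_excluded.update(x for x in rule.skipped_items if x in item_set)
            walk(idx + 1, current, new_excluded)
            del current[item_id]

    walk(0, {}, set())
    return patterns


def _pattern_record(pattern: Mapping[str, object]) -> ResponseRecord:
    answers = {
        k: (RULE_SKIPPED if v is _SKIP else answered(v)) for k, v in pattern.items()
    }
    return ResponseRecord("_pattern", answers)


def _dep_class(record: ResponseRecord, rules: Ruleset) -> str:
    res = classify_depression(record, rules)
    if res.status is not SyndromeStatus.MET:
        return "none"
    episodes = res.detail["episode_count"]
    if episodes is None:
        return "none"  # unreachable for fully answered patterns
    return "recurrent" if episodes >= rules.depression.recurrent_min_episodes else "single"


_BOOL_BLOCK_CLASSIFIERS = {
    "mania": classify_mania,
    "gad": classify_gad,
    "alcohol_hazardous": classify_alcohol,
    "ptsd_current": classify_ptsd,
    "unusual_experiences": classify_unusual_experiences,
    "self_harm": classify_self_harm,
    "addiction": classify_addiction,
}


class EmissionModel:
    """Precomputed consistency classes for every emitted scale.

    Built once per (instrument, ruleset).  Sampling is uniform within a
    class; for gated scales each class is additionally partitioned by
    whether the respondent engaged the screen, so that the configured share
    of true-negatives takes the screen-negative path instead of the
    (combinatorially dominant) engaged-but-unmet patterns.
    """

    def __init__(self, spec: InstrumentSpec, rules: Ruleset) -> None:
        self.spec = spec
        self.rules = rules
        self.classes: dict[str, dict[object, dict[str, list]]] = {}
        r = rules
        self._engaged_fns = {
            "depression": lambda rec: (
                rec.value(r.depression.screen_mood_item) == 1
                or rec.value(r.depression.screen_anhedonia_item) == 1
            ),
            "mania": lambda rec: (
                rec.value(r.mania.screen_elated_item) == 1
                or rec.value(r.mania.screen_irritable_item) == 1
            ),
            "gad": lambda rec: rec.value(r.gad.screen_item) == 1,
            "alcohol_hazardous": lambda rec: rec.value(r.alcohol.items[0]) != 0,
        }
        dep_items = [
            r.depression.screen_mood_item,
            r.depression.screen_anhedonia_item,
            r.depression.core_most_item,
            r.depression.anhedonia_symptom_item,
            *r.depression.other_symptom_items,
            r.depression.duration_item,
            r.depression.impairment_item,
            r.depression.episodes_item,
        ]
        self._build("depression", dep_items, lambda rec: _dep_class(rec, rules))
        blocks = {
            "mania": [
                r.mania.screen_elated_item,
                r.mania.screen_irritable_item,
                *r.mania.symptom_items,
                r.mania.duration_item,
            ],
            "gad": [
                r.gad.screen_item,
                r.gad.duration_item,
                r.gad.excessive_item,
                r.gad.control_item,
                *r.gad.symptom_items,
            ],
            "alcohol_hazardous": list(r.alcohol.items),
            "ptsd_current": list(r.ptsd.items),
            "unusual_experiences": list(r.unusual_experiences.items),
            "self_harm": [r.self_harm.item],
            "addiction": [r.addiction.item],
        }
        for name, items in blocks.items():
            fn = _BOOL_BLOCK_CLASSIFIERS[name]
            self._build(name, items, lambda rec, fn=fn: fn(rec, rules).met)
        self._build(
            "childhood_adversity",
            list(r.childhood_trauma.item_thresholds),
            lambda rec: screen_childhood_trauma(rec, rules) is TriState.MET,
        )
        self._build(
            "trauma_exposure",
            list(r.trauma_triggers.items),
            lambda rec: screen_trauma_exposure(rec, rules) is TriState.MET,
        )
        # adult adversity and loneliness share the confiding item: one joint
        # block classified by the pair of screen outcomes
        joint_items = sorted(
            set(r.adult_adversity.items) | {r.loneliness.lonely_item, r.loneliness.confide_item},
            key=spec.order,
        )
        self._build(
            "adversity_loneliness",
            joint_items,
            lambda rec: (
                screen_adult_adversity(rec, rules) is TriState.MET,
                screen_loneliness(rec, rules) is TriState.MET,
            ),
        )

    def _build(self, name: str, item_ids: Sequence[str], key_fn) -> None:
        engaged_fn = self._engaged_fns.get(name)
        classes: dict[object, dict[str, list]] = {}
        for pattern in enumerate_block_patterns(self.spec, item_ids):
            rec = _pattern_record(pattern)
            key = key_fn(rec)
            bucket = classes.setdefault(key, {"all": [], "engaged": [], "screened_out": []})
            bucket["all"].append(pattern)
            if engaged_fn is not None:
                bucket["engaged" if engaged_fn(rec) else "screened_out"].append(pattern)
        if len(classes) < 2:
            raise ConfigError(
                f"scale {name!r} has a consistency class with no patterns "
                "(mis-specified ruleset or instrument)"
            )
        self.classes[name] = classes

    def draw(
        self,
        name: str,
        key: object,
        rng: np.random.Generator,
        engage_rate: float | None = None,
    ) -> dict[str, object]:
        bucket = self.classes[name].get(key)
        if bucket is None:
            raise ConfigError(f"scale {name!r}: no pattern consistent with class {key!r}")
        pool = bucket["all"]
        if engage_rate is not None and bucket["engaged"] and bucket["screened_out"]:
            pool = (
                bucket["engaged"]
                if rng.random() < engage_rate
                else bucket["screened_out"]
            )
        return pool[int(rng.integers(len(pool)))]


def _flip(true_value: bool, fid: Fidelity, rng: np.random.Generator) -> bool:
    """Classification-consistency coin: returns the emitted class."""
    if true_value:
        return rng.random() < fid.sensitivity
    return rng.random() >= fid.specificity


def _apply_pattern(answers: dict[str, Answer], pattern: Mapping[str, object]) -> None:
    for item_id, value in pattern.items():
        answers[item_id] = RULE_SKIPPED if value is _SKIP else answered(value)


def _reconcile_skips(spec: InstrumentSpec, record: ResponseRecord) -> None:
    """Re-derive rule-skipped marks after censoring altered trigger answers."""
    apply_skip_marks(spec, record)


def _emit(
    profile: LatentProfile,
    model: EmissionModel,
    config: CohortConfig,
    rng: np.random.Generator,
) -> ResponseRecord:
    spec = model.spec
    answers: dict[str, Answer] = {}
    beh = config.behaviour_model
    any_syndrome = any(
        profile.node_state(s) for s in LATENT_NODES if s != "addiction"
    )

    # demographics / baseline-style fields (direct recodes of the profile)
    answers["AGE"] = answered(profile.age_years)
    answers["SEX"] = answered(1 if profile.sex == "male" else 0)
    answers["EDU_DEGREE"] = answered(int(profile.degree_holder))
    answers["TOWNSEND_Q"] = answered(profile.townsend_quintile)
    if profile.renter:
        tenure = 3 if rng.random() < 0.5 else 4
    else:
        tenure = int(rng.choice([1, 2, 5, 6], p=[0.52, 0.40, 0.04, 0.04]))
    answers["TENURE"] = answered(tenure)
    answers["LONGILL"] = answered(int(profile.longstanding_illness))
    answers["NEUROTICISM"] = answered(profile.neuroticism_score)
    p_smoke = float(beh.get("smoked_base", 0.40)) + (
        float(beh.get("smoked_any_syndrome_extra", 0.15)) if any_syndrome else 0.0
    )
    answers["SMOKED_EVER"] = answered(int(rng.random() < p_smoke))
    p_cann = float(beh.get("cannabis_base", 0.18)) + (
        float(beh.get("cannabis_any_syndrome_extra", 0.12)) if any_syndrome else 0.0
    )
    answers["CANNABIS_EVER"] = answered(int(rng.random() < p_cann))
    answers["PHYS_ACT"] = answered(
        int(rng.random() < float(beh.get("physical_activity_rate", 0.60)))
    )
    p_alone = float(beh.get("live_alone_base", 0.17)) + (
        float(beh.get("live_alone_lonely_extra", 0.20)) if profile.loneliness else 0.0
    )
    answers["LIVE_ALONE"] = answered(int(rng.random() < p_alone))
    contact_key = "contact_probs_lonely" if profile.loneliness else "contact_probs"
    contact_probs = np.asarray(
        beh.get(contact_key, [0.3, 0.4, 0.15, 0.1, 0.05]), dtype=float
    )
    answers["CONTACT_FREQ"] = answered(
        int(rng.choice(5, p=contact_probs / contact_probs.sum()))
    )
    p_group = float(beh.get("group_activity_base", 0.55)) - (
        float(beh.get("group_activity_lonely_penalty", 0.20)) if profile.loneliness else 0.0
    )
    answers["GROUP_ACT"] = answered(int(rng.random() < p_group))

    # self-reported professional diagnoses
    dx_model = config.diagnosis_model
    tick_p: dict[int, float] = {}
    coding = spec.item(model.rules.diagnoses.item).coding
    label_to_code = {v: k for k, v in coding.items()}
    for label, p in (dx_model.get("background") or {}).items():
        tick_p[label_to_code[label]] = float(p)
    for syndrome, label_probs in (dx_model.get("given_syndrome") or {}).items():
        if profile.node_state(syndrome):
            for label, p in label_probs.items():
                code = label_to_code[label]
                tick_p[code] = max(tick_p.get(code, 0.0), float(p))
    ticks = frozenset(c for c, p in tick_p.items() if rng.random() < p)
    answers[model.rules.diagnoses.item] = answered(
        ticks if ticks else frozenset({model.rules.diagnoses.none_code})
    )

    # syndrome scales: fidelity coin then uniform draw from the class
    dep_fid = config.fidelity("depression")
    if profile.depression_any:
        if rng.random() < dep_fid.sensitivity:
            dep_key = "recurrent" if profile.true_state["depression_recurrent"] else "single"
        else:
            dep_key = "none"
    else:
        if rng.random() >= dep_fid.specificity:
            dep_key = "recurrent" if rng.random() < config.recurrent_share else "single"
        else:
            dep_key = "none"
    engage = config.screen_engage_given_negative
    _apply_pattern(
        answers,
        model.draw(
            "depression",
            dep_key,
            rng,
            engage_rate=engage.get("depression") if dep_key == "none" else None,
        ),
    )
    for name in (
        "mania",
        "gad",
        "alcohol_hazardous",
        "ptsd_current",
        "unusual_experiences",
        "self_harm",
        "addiction",
    ):
        emitted = _flip(profile.node_state(name), config.fidelity(name), rng)
        _apply_pattern(
            answers,
            model.draw(
                name,
                emitted,
                rng,
                engage_rate=engage.get(name) if not emitted else None,
            ),
        )

    # risk screens: exact recodes of the latent flags
    _apply_pattern(
        answers, model.draw("childhood_adversity", profile.childhood_adversity, rng)
    )
    _apply_pattern(answers, model.draw("trauma_exposure", profile.trauma_exposure, rng))
    _apply_pattern(
        answers,
        model.draw(
            "adversity_loneliness",
            (profile.adult_adversity, profile.loneliness),
            rng,
        ),
    )

    record = ResponseRecord(profile.respondent_id, answers)

    # voluntary nonresponse
    if config.decline_rate > 0:
        answered_items = [
            it for it in spec.item_ids if record.status(it) is Status.ANSWERED
        ]
        coins = rng.random(len(answered_items))
        for it, u in zip(answered_items, coins):
            if u < config.decline_rate:
                record.answers[it] = DECLINED
        _reconcile_skips(spec, record)

    # partial completion: abandon at a uniformly chosen presented item
    if config.partial_rate > 0 and rng.random() < config.partial_rate:
        presented = sorted(resolve_presented_items(spec, record), key=spec.order)
        if len(presented) > 1:
            cut = int(rng.integers(1, len(presented)))
            cut_order = spec.order(presented[cut])
            for item_id in spec.item_ids:
                if spec.order(item_id) >= cut_order and record.status(item_id) in (
                    Status.ANSWERED,
                    Status.DECLINED,
                ):
                    record.answers[item_id] = ABSENT
            _reconcile_skips(spec, record)

    return record


_MODEL_CACHE: dict[tuple[str, str], EmissionModel] = {}


def _emission_model(spec: InstrumentSpec, rules: Ruleset) -> EmissionModel:
    key = (spec.version, rules.version)
    model = _MODEL_CACHE.get(key)
    if model is None or model.spec is not spec or model.rules is not rules:
        model = EmissionModel(spec, rules)
        _MODEL_CACHE[key] = model
    return model


def emit_responses(
    profile: LatentProfile,
    spec: InstrumentSpec,
    rules: Ruleset,
    config: CohortConfig,
    rng: np.random.Generator,
) -> ResponseRecord:
    """Emit one respondent's skip-consistent record from their latent truth."""
    return _emit(profile, _emission_model(spec, rules), config, rng)


def generate_cohort(
    config: CohortConfig,
    spec: InstrumentSpec,
    rules: Ruleset,
    seed: int | None = None,
) -> tuple[list[ResponseRecord], TruthTable]:
    """Sample latent profiles and emit their response records.

    ``seed`` overrides ``config.seed``.  The latent draw and each
    respondent's emission use independent substreams derived from the seed
    by counter, so output is independent of generation order.
    """
    base = config.seed if seed is None else seed
    latent_rng = np.random.default_rng(np.random.SeedSequence([base, 1]))
    profiles = sample_latent(config, latent_rng)
    model = _emission_model(spec, rules)
    records = [
        _emit(p, model, config, np.random.default_rng(np.random.SeedSequence([base, 2, i])))
        for i, p in enumerate(profiles)
    ]
    return records, TruthTable(profiles)
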