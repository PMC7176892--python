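"""Shared fixtures: bundled instrument/ruleset, record builder, and a
moderate perfect-fidelity synthetic cohort reused across test modules."""

from __future__ import annotations

import pytest
from hypothesis import settings

from mhqtools.instrument import (
    DECLINED,
    ResponseRecord,
    answered,
    apply_skip_marks,
)
from mhqtools.ruleset import default_ruleset
from mhqtools.instrument import default_instrument
from mhqtools.simulate import default_cohort_config, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec():
    return default_instrument()


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


@pytest.fixture(scope="session")
def make_record(spec):
    """Build a record from answered codes (use the string ``"declined"`` for
    a prefer-not-to-answer); items excluded by the skip rules are marked
    rule-skipped, remaining presented items stay absent."""

    def _make(values: dict, rid: str = "T1") -> ResponseRecord:
        answers = {}
        for item, v in values.items():
            answers[item] = DECLINED if v == "declined" else answered(v)
        return apply_skip_marks(spec, ResponseRecord(rid, answers))

    return _make


@pytest.fixture(scope="session")
def perfect_cohort(spec, rules):
    """n=2000 cohort at default prevalences, perfect fidelity, no censoring."""
    cfg = default_cohort_config(
        n=2000,
        seed=7,
        emission_fidelity={},
        decline_rate=0.0,
        partial_rate=0.0,
    )
    records, truth = generate_cohort(cfg, spec, rules)
    return records, truth


@pytest.fixture(scope="session")
def perfect_phenotypes(perfect_cohort, spec, rules):
    from mhqtools.phenotypes import classify_all

    records, truth = perfect_cohort
    return classify_all(records, spec, rules), truth


@pytest.fixture(scope="session")
def perfect_risks(perfect_cohort, spec, rules):
    from mhqtools.risk import derive_all_risks

    records, _ = perfect_cohort
    return derive_all_risks(records, spec, rules)
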