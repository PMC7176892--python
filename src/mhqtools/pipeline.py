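"""End-to-end orchestration: simulate -> validate -> phenotype -> tabulate.

A run is configured by a :class:`RunConfig` (paths, seed, table selection),
produces stage outputs as standalone delimited-text files, and writes a
manifest with versions, the seed, and a checksum per artifact.  Outputs are
byte-identical under a fixed seed and config; timings go to the log only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as mio
from .instrument import (
    Completion,
    InstrumentSpec,
    completion_status,
    default_instrument,
    load_instrument,
    validate_responses,
)
from .phenotypes import SYNDROMES, SyndromeStatus, classify_all
from .risk import derive_all_risks
from .ruleset import Ruleset, default_ruleset, load_ruleset
from .simulate import default_cohort_config, generate_cohort, load_cohort_config
from .tabulate import (
    characteristics_by_mood_group,
    characteristics_by_stratum,
    comorbidity_crosstab,
    diagnosis_prevalence,
    mood_group_comorbidity,
    stratify_by_sex,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]

logger = logging.getLogger("mhqtools")

_TABLES = ("table1", "table2", "table3", "sex", "mood")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    instrument_path: Path | None = None  # None -> bundled default
    ruleset_path: Path | None = None
    cohort_config_path: Path | None = None
    responses_path: Path | None = None  # set -> simulation stage skipped
    n: int | None = None
    seed: int | None = None
    tables: tuple[str, ...] = _TABLES
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("instrument_path", "ruleset_path", "cohort_config_path", "responses_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{name} does not exist: {p}")
        bad = [t for t in self.tables if t not in _TABLES]
        if bad:
            raise PipelineError(f"unknown tables requested: {bad}")


def load_run_config(path: str | Path, out_dir: str | Path | None = None) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    base = Path(path).parent

    def _p(key: str) -> Path | None:
        v = doc.get(key)
        return (base / v) if v is not None else None

    return RunConfig(
        out_dir=Path(out_dir) if out_dir is not None else base / doc.get("out_dir", "out"),
        instrument_path=_p("instrument"),
        ruleset_path=_p("ruleset"),
        cohort_config_path=_p("cohort_config"),
        responses_path=_p("responses"),
        n=doc.get("n"),
        seed=doc.get("seed"),
        tables=tuple(doc.get("tables", _TABLES)),
        log_level=str(doc.get("log_level", "INFO")),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all requested stages; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec: InstrumentSpec = (
        load_instrument(config.instrument_path)
        if config.instrument_path is not None
        else default_instrument()
    )
    rules: Ruleset = (
        load_ruleset(config.ruleset_path)
        if config.ruleset_path is not None
        else default_ruleset()
    )

    manifest: dict = {
        "instrument_version": spec.version,
        "ruleset_version": rules.version,
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
    }

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        result = fn()
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        manifest["stages"].append(name)
        return result

    def _register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    # --- simulate or load -------------------------------------------------
    if config.responses_path is not None:
        manifest["input_provenance"] = str(config.responses_path)

        def _load():
            return mio.read_responses_wide(config.responses_path, spec)

        records = _stage("load_responses", _load)
    else:
        cohort_cfg = (
            load_cohort_config(config.cohort_config_path, n=config.n, seed=config.seed)
            if config.cohort_config_path is not None
            else default_cohort_config(n=config.n, seed=config.seed)
        )
        manifest["seed"] = cohort_cfg.seed

        def _simulate():
            recs, truth = generate_cohort(cohort_cfg, spec, rules)
            responses_path = out / "responses.tsv"
            mio.write_responses_wide(recs, spec, responses_path)
            _register("responses", responses_path)
            truth_path = out / "truth.tsv"
            truth.to_frame().to_csv(truth_path, sep="\t", index=False)
            _register("truth", truth_path)
            return recs

        records = _stage("simulate", _simulate)

    dict_path = out / "data_dictionary.tsv"
    mio.write_data_dictionary(spec, dict_path)
    _register("data_dictionary", dict_path)

    # --- validate + QC ----------------------------------------------------
    def _qc():
        completions = {c.value: 0 for c in Completion}
        n_violations = 0
        for rec in records:
            n_violations += len(validate_responses(spec, rec))
            completions[completion_status(spec, rec).value] += 1
        return completions, n_violations

    completions, n_violations = _stage("validate", _qc)

    # --- phenotype --------------------------------------------------------
    def _phenotype():
        phen = classify_all(records, spec, rules, skip_invalid=True, log=logger.warning)
        path = out / "phenotypes.tsv"
        mio.write_phenotypes(phen, path, spec.version, rules.version)
        _register("phenotypes", path)
        risks = derive_all_risks(records, spec, rules)
        rpath = out / "risk_profiles.tsv"
        mio.write_risks(risks, rpath, spec.version, rules.version)
        _register("risk_profiles", rpath)
        return phen, risks

    phenotypes, risks = _stage("phenotype", _phenotype)

    qc = {
        "n_records": len(records),
        "completion": completions,
        "validation_violations": n_violations,
        "unassessable_per_syndrome": {
            s: sum(
                1
                for p in phenotypes
                if p.status(s) is SyndromeStatus.UNASSESSABLE
            )
            for s in SYNDROMES
        },
        "mood_group_undefined": sum(1 for p in phenotypes if p.mood_group is None),
    }
    qc_path = out / "qc_report.json"
    qc_path.write_text(json.dumps(qc, indent=2, sort_keys=True) + "\n")
    _register("qc_report", qc_path)

    # --- tabulate ---------------------------------------------------------
    def _tabulate():
        if "table1" in config.tables:
            path = out / "table1_diagnoses.tsv"
            diagnosis_prevalence(phenotypes).to_csv(path, sep="\t", index=False)
            _register("table1_diagnoses", path)
        if "table2" in config.tables:
            ct = comorbidity_crosstab(phenotypes)
            path = out / "table2_comorbidity.tsv"
            with open(path, "w") as fh:
                fh.write("# row-conditional percentages; counts below\n")
                ct.to_frame("pct").to_csv(fh, sep="\t")
                fh.write("#\n# pair counts\n")
                ct.to_frame("counts").to_csv(fh, sep="\t")
                fh.write("#\n# pairwise denominators\n")
                ct.to_frame("denominators").to_csv(fh, sep="\t")
            _register("table2_comorbidity", path)
        if "table3" in config.tables:
            st = characteristics_by_stratum(phenotypes, risks)
            path = out / "table3_characteristics.tsv"
            st.to_frame().to_csv(path, sep="\t")
            _register("table3_characteristics", path)
        if "sex" in config.tables:
            st = stratify_by_sex(phenotypes, risks)
            path = out / "table_sex_stratified.tsv"
            st.to_frame().to_csv(path, sep="\t")
            _register("table_sex_stratified", path)
        if "mood" in config.tables:
            st = characteristics_by_mood_group(phenotypes, risks)
            path = out / "table_mood_characteristics.tsv"
            st.to_frame().to_csv(path, sep="\t")
            _register("table_mood_characteristics", path)
            path = out / "table_mood_comorbidity.tsv"
            mood_group_comorbidity(phenotypes).to_csv(path, sep="\t", index=False)
            _register("table_mood_comorbidity", path)

    _stage("tabulate", _tabulate)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
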