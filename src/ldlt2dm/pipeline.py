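"""End-to-end orchestration: simulate → build cohort → phenotype →
associate → sensitivity → report.

Every run is deterministic under a fixed :class:`RunConfig`: the report is
byte-identical across reruns. Each artifact records the run's seed and a
hash of the full configuration. The pipeline honours the prespecified
two-phase design: when the discovery gate fails, it stops after phase 1
(the report still records the discovery results) unless
``force_validation`` is set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import cohort as cohort_mod
from . import phenotype as pheno
from .config import RunConfig, config_hash
from .phecodes import PhecodeMap, T2DM_PHECODES
from .simulate import (
    CODE_COLUMNS,
    LAB_COLUMNS,
    MED_COLUMNS,
    PATIENT_COLUMNS,
    EhrTables,
    generate_population,
    summarize_population,
    write_tables,
)

__all__ = ["SchemaError", "run_pipeline", "load_tables", "validate_tables"]

logger = logging.getLogger(__name__)

_REQUIRED = {
    "patients": PATIENT_COLUMNS,
    "labs": LAB_COLUMNS,
    "codes": CODE_COLUMNS,
    "meds": MED_COLUMNS,
}
_DATE_COLUMNS = {"patients": ["birth_date"], "labs": ["date"], "codes": ["date"], "meds": ["date"]}


class SchemaError(ValueError):
    """An input table is missing required columns or has unparseable values."""


def validate_tables(tables: EhrTables) -> None:
    problems = []
    for name, required in _REQUIRED.items():
        df = getattr(tables, name)
        missing = [c for c in required if c not in df.columns]
        if missing:
            problems.append(f"{name}: missing columns {missing}")
    if problems:
        raise SchemaError("; ".join(problems))


def load_tables(config: RunConfig) -> EhrTables:
    """Read the four input CSVs, or simulate them when paths are unset."""
    paths = (config.patients_csv, config.labs_csv, config.codes_csv, config.meds_csv)
    if all(p is None for p in paths):
        return generate_population(config.simulation)
    if any(p is None for p in paths):
        raise SchemaError("either all four table paths or none must be given")
    frames = {}
    for name, path in zip(("patients", "labs", "codes", "meds"), paths):
        df = pd.read_csv(path, comment="#")
        for col in _DATE_COLUMNS[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col], errors="coerce")
        frames[name] = df
    tables = EhrTables(frames["patients"], frames["labs"], frames["codes"], frames["meds"], None)
    validate_tables(tables)
    return tables


@dataclass
class PipelineResult:
    report: dict
    cohort: pd.DataFrame
    results: pd.DataFrame
    gate_stopped: bool


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (pd.Timestamp, np.datetime64)):
        return str(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_csv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False, date_format="%Y-%m-%d")


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute all stages in order and assemble the report bundle."""
    chash = config_hash(config)
    stamp = f"seed={config.seed} config_hash={chash}"
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    tables = load_tables(config)
    validate_tables(tables)
    logger.info("stage=load patients=%d labs=%d codes=%d meds=%d", *(len(getattr(tables, k)) for k in ("patients", "labs", "codes", "meds")))
    if write and tables.truth is not None:  # simulated input: persist for audit
        write_tables(tables, out, header_comment=stamp)

    if config.phecode_map_csv:
        pmap = PhecodeMap.from_csv(config.phecode_map_csv, config.phecode_exclusions_csv)
    else:
        pmap = PhecodeMap.bundled()

    # --- cohort -------------------------------------------------------------
    ldl_records = cohort_mod.filter_ldl_measurements(
        tables.labs, tables.codes, tables.meds, tables.patients, config
    )
    cohort = cohort_mod.assign_groups(ldl_records, config)
    if cohort.empty:
        raise SchemaError("no candidate LDL-C determinations in the input tables")
    cohort = cohort_mod.split_phases(cohort, config.seed, config.discovery_fraction)
    attrition = cohort_mod.attrition_report(ldl_records, cohort)
    logger.info("stage=cohort %s", attrition["groups"])

    # --- phenotypes & covariates --------------------------------------------
    included_ids = cohort.loc[cohort["group"].isin(["low", "normal"]), "patient_id"]
    calls = [
        pheno.assign_phecode_status(tables.codes, pmap, phecode, patient_ids=included_ids)
        for phecode in T2DM_PHECODES
    ]
    calls.append(
        pheno.t2dm_algorithm(tables.codes, tables.labs, tables.meds, patient_ids=included_ids)
    )
    phenotypes = pd.concat(calls, ignore_index=True)
    covariates = pheno.derive_covariates(tables.patients, tables.labs, tables.codes)
    logger.info("stage=phenotype calls=%d covariate_rows=%d", len(phenotypes), len(covariates))

    summary = summarize_population(cohort, covariates, tables.patients)

    # --- phase 1 ------------------------------------------------------------
    discovery = assoc.discovery_screen(cohort, phenotypes, covariates, alpha=config.alpha)
    logger.info("stage=discovery min_p=%.3g gate=%s", discovery.min_p, discovery.gate)

    all_rows = [r | {"stage": "discovery"} for r in discovery.results.to_dict("records")]
    gate_stopped = not discovery.gate and not config.force_validation

    report: dict = {
        "seed": config.seed,
        "config_hash": chash,
        "attrition": attrition,
        "discovery": {
            "threshold": discovery.threshold,
            "min_p": discovery.min_p,
            "gate": discovery.gate,
        },
        "population_summary": summary.to_dict("records"),
    }

    interactions: dict[str, float] = {}
    if not gate_stopped:
        frame = assoc.build_analysis_frame(
            cohort, phenotypes, covariates, "t2dm_algorithm", phase="validation"
        )
        logger.info("stage=validation rows=%d cases=%d", len(frame), int(frame["outcome"].sum()))
        primary = assoc.primary_analysis(frame, alpha=config.alpha)
        strata = assoc.stratified_analysis(frame, alpha=config.alpha)
        sens = assoc.sensitivity_suite(
            frame, ldl_records, tables.codes, tables.labs, tables.meds,
            tables.patients, pmap, config, alpha=config.alpha,
        )
        for variable in ("sex", "race", "bmi_category"):
            try:
                p, _ = assoc.interaction_test(frame, variable, alpha=config.alpha)
                interactions[variable] = p
            except ValueError as exc:
                logger.warning("interaction %s: %s", variable, exc)
                interactions[variable] = float("nan")
        all_rows += [r.to_row() | {"stage": "primary"} for r in primary]
        all_rows += [r.to_row() | {"stage": "stratified"} for r in strata]
        all_rows += [r.to_row() | {"stage": "sensitivity"} for r in sens]
        report["interactions"] = interactions
        report["validation_n"] = {
            "rows": int(len(frame)),
            "cases": int(frame["outcome"].sum()),
            "controls": int((1 - frame["outcome"]).sum()),
        }

    results = pd.DataFrame(all_rows)
    report["results"] = results.to_dict("records")
    report["gate_stopped"] = gate_stopped

    if write:
        _write_csv(ldl_records, out / "ldl_records.csv", stamp)
        _write_csv(cohort, out / "cohort.csv", stamp)
        _write_csv(phenotypes, out / "phenotypes.csv", stamp)
        _write_csv(covariates.round(6), out / "covariates.csv", stamp)
        _write_csv(results, out / "results.csv", stamp)
        (out / "attrition.json").write_text(
            json.dumps(attrition, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
        logger.info("stage=report out_dir=%s", out)

    return PipelineResult(report=report, cohort=cohort, results=results, gate_stopped=gate_stopped)
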