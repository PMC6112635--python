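"""Monte-Carlo harnesses: parameter recovery, CI coverage, and type-I
calibration of the interaction test.

These experiments run the *full* pipeline path — generation, cohort
construction, algorithmic phenotyping, covariate derivation, model fit —
so they exercise every stage, not just the estimator. Seeds are derived
deterministically from a base seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np

from . import association as assoc
from . import cohort as cohort_mod
from . import phenotype as pheno
from .config import RunConfig, SimulationConfig
from .simulate import generate_population
from .stats import ADJUSTMENT_FULL, ModelSpec, fit_logistic

__all__ = [
    "adjusted_fit_once",
    "ci_coverage",
    "interaction_type1_rate",
    "unadjusted_marginal_fit_once",
]

logger = logging.getLogger(__name__)


def _analysis_frame(sim: SimulationConfig, run: RunConfig | None = None):
    run = run or RunConfig(simulation=sim, seed=sim.seed)
    tables = generate_population(sim, return_truth=False)
    records = cohort_mod.filter_ldl_measurements(
        tables.labs, tables.codes, tables.meds, tables.patients, run
    )
    cohort = cohort_mod.assign_groups(records, run)
    cohort = cohort_mod.split_phases(cohort, sim.seed, run.discovery_fraction)
    included = cohort.loc[cohort["group"].isin(["low", "normal"]), "patient_id"]
    calls = pheno.t2dm_algorithm(tables.codes, tables.labs, tables.meds, patient_ids=included)
    covariates = pheno.derive_covariates(tables.patients, tables.labs, tables.codes)
    return assoc.build_analysis_frame(cohort, calls, covariates, "t2dm_algorithm", phase=None)


def adjusted_fit_once(
    seed: int,
    n_patients: int = 20_000,
    true_or: float = 2.0,
    base: SimulationConfig | None = None,
):
    """Simulate one population and return the fully adjusted exposure fit."""
    base = base or SimulationConfig()
    sim = replace(base, n_patients=n_patients, seed=seed, true_log_or_low_ldl=math.log(true_or))
    frame = _analysis_frame(sim)
    result, _ = fit_logistic(frame, ModelSpec(adjustment_set=ADJUSTMENT_FULL))
    return result


def unadjusted_marginal_fit_once(seed: int, n_patients: int = 20_000, true_or: float = 2.0):
    """Null-covariate, contamination-free design where the marginal
    (unadjusted) odds ratio equals the conditional one."""
    sim = SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        true_log_or_low_ldl=math.log(true_or),
        covariate_effects={"age": 0.0, "male": 0.0, "african_ancestry": 0.0, "bmi": 0.0},
    ).zero_contamination()
    frame = _analysis_frame(sim)
    result, _ = fit_logistic(frame, ModelSpec(adjustment_set=()))
    return result


def ci_coverage(
    n_seeds: int = 100,
    base_seed: int = 202_601,
    n_patients: int = 20_000,
    true_or: float = 2.0,
) -> dict:
    """How often the fully adjusted 95% CI covers the true odds ratio."""
    covered = 0
    estimates = []
    for i in range(n_seeds):
        result = adjusted_fit_once(base_seed + i, n_patients=n_patients, true_or=true_or)
        estimates.append(result.or_estimate)
        if result.converged and result.ci_low <= true_or <= result.ci_high:
            covered += 1
    logger.info("ci_coverage: %d/%d cover OR=%.2f", covered, n_seeds, true_or)
    return {
        "covered": covered,
        "n_seeds": n_seeds,
        "true_or": true_or,
        "mean_or": float(np.mean(estimates)),
        "median_or": float(np.median(estimates)),
    }


def interaction_type1_rate(
    n_seeds: int = 200,
    base_seed: int = 202_602,
    n_patients: int = 6_000,
    variable: str = "sex",
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the interaction Wald test when no interaction exists.

    The generator draws T2DM from an additive log-odds model, so every
    exposure×covariate product effect is truly zero; a calibrated test
    rejects at ≈ alpha.
    """
    rejections = 0
    used = 0
    for i in range(n_seeds):
        sim = SimulationConfig(n_patients=n_patients, seed=base_seed + i)
        frame = _analysis_frame(sim)
        try:
            p, result = assoc.interaction_test(frame, variable)
        except ValueError:
            continue
        if not result.converged or not np.isfinite(p):
            continue
        used += 1
        if p < alpha:
            rejections += 1
    rate = rejections / used if used else float("nan")
    logger.info("interaction_type1_rate: %d/%d rejected (%.3f)", rejections, used, rate)
    return {"rejections": rejections, "n_used": used, "n_seeds": n_seeds, "rate": rate}
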