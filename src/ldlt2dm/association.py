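"""Two-phase association analyses.

Phase 1 (discovery): the six type-2-diabetes phecodes are each tested with
an age/race/sex-adjusted logistic model; the study proceeds to phase 2
only when the smallest adjusted p-value clears the Bonferroni threshold
0.05/6 ≈ 0.0083.

Phase 2 (validation): the algorithmic T2DM phenotype is analysed
unadjusted, demographically adjusted (age, race, sex, BMI) and fully
adjusted (adding EHR length, HDL-C, triglycerides); prespecified strata
(sex, race, BMI category, LDL-C refinement), interaction tests, and six
sensitivity restrictions re-fit the fully adjusted model on filtered
cohorts.

All fits are complete-case; each result carries its own case/control
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .phecodes import PhecodeMap, T2DM_PHECODES
from .stats import (
    ADJUSTMENT_DEMOGRAPHIC,
    ADJUSTMENT_FULL,
    ADJUSTMENT_NONE,
    AssociationResult,
    ModelSpec,
    SeparationError,
    fit_logistic,
    wald_interaction_p,
)

__all__ = [
    "build_analysis_frame",
    "bmi_category",
    "discovery_screen",
    "primary_analysis",
    "stratified_analysis",
    "interaction_test",
    "sensitivity_suite",
    "DiscoveryOutcome",
]

logger = logging.getLogger(__name__)

#: ICD-9 lists for the sensitivity restrictions
TRANSPLANT_ICD9 = ["V42.0", "V42.1", "V42.2", "V42.5", "V42.6", "V42.7", "V42.81", "V42.82"]
STROKE_ICD9 = ["434.91", "334.9", "435", "435.8", "435.9"]
STROKE_ICD9_SUBSTITUTED = ["434.91", "433.91", "435", "435.8", "435.9"]
RENAL_PHECODES = ["585.31", "585.32", "585.34"]
EGFR_THRESHOLD = 29.0  # ml/min


def bmi_category(bmi: pd.Series) -> pd.Series:
    """WHO adult categories; below 18.5 is 'underweight' (excluded from
    BMI-stratified fits but kept in the primary model)."""
    return pd.cut(
        bmi,
        bins=[-np.inf, 18.5, 25.0, 30.0, np.inf],
        labels=["underweight", "normal", "overweight", "obese"],
        right=False,
    ).astype(object)


def build_analysis_frame(
    cohort: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    phenotype_id: str = "t2dm_algorithm",
    phase: str | None = None,
) -> pd.DataFrame:
    """Merge cohort, phenotype calls and covariates into a model-ready frame.

    Keeps case/control rows only (the phenotype's 'excluded' patients drop
    out) and encodes exposure = 1 for the low LDL-C group.
    """
    ph = phenotypes[phenotypes["phenotype_id"] == phenotype_id]
    df = cohort[cohort["group"].isin(["low", "normal"])]
    if phase is not None:
        df = df[df["phase"] == phase]
    df = df.merge(ph[["patient_id", "status"]], on="patient_id", how="inner")
    df = df[df["status"].isin(["case", "control"])].copy()
    df["outcome"] = (df["status"] == "case").astype(int)
    df["exposure"] = (df["group"] == "low").astype(int)
    df = df.merge(covariates, on="patient_id", how="left")
    df["bmi_category"] = bmi_category(df["bmi_median"])
    return df


@dataclass(frozen=True)
class DiscoveryOutcome:
    results: pd.DataFrame
    threshold: float
    min_p: float
    gate: bool


def discovery_screen(
    cohort: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> DiscoveryOutcome:
    """Phase 1 screen over the six T2DM phecodes in the discovery sample.

    Each phecode is fitted with age/race/sex adjustment; the gate opens
    when the smallest p-value is below alpha divided by the number of
    phecodes tested (0.05/6 → 0.0083).
    """
    spec = ModelSpec(adjustment_set=("age", "race", "sex"))
    rows = []
    for phecode in T2DM_PHECODES:
        frame = build_analysis_frame(cohort, phenotypes, covariates, phecode, phase="discovery")
        try:
            result, _ = fit_logistic(frame, ModelSpec(outcome=phecode, adjustment_set=spec.adjustment_set))
        except (SeparationError, ValueError) as exc:
            logger.warning("discovery_screen: %s not fittable (%s)", phecode, exc)
            rows.append(
                AssociationResult(
                    np.nan, np.nan, np.nan, np.nan,
                    n_cases=int(frame["outcome"].sum()) if len(frame) else 0,
                    n_controls=int((1 - frame["outcome"]).sum()) if len(frame) else 0,
                    model=f"{phecode} ~ exposure | age+race+sex",
                    converged=False,
                    note=str(exc),
                ).to_row()
                | {"phenotype_id": phecode}
            )
            continue
        rows.append(result.to_row() | {"phenotype_id": phecode})
    results = pd.DataFrame(rows)
    threshold = alpha / len(T2DM_PHECODES)
    pvals = results["p_value"].dropna()
    min_p = float(pvals.min()) if len(pvals) else float("nan")
    gate = bool(len(pvals)) and min_p < threshold
    return DiscoveryOutcome(results=results, threshold=threshold, min_p=min_p, gate=gate)


def primary_analysis(frame: pd.DataFrame, alpha: float = 0.05) -> list[AssociationResult]:
    """Unadjusted, demographically adjusted and fully adjusted fits."""
    out = []
    for adj in (ADJUSTMENT_NONE, ADJUSTMENT_DEMOGRAPHIC, ADJUSTMENT_FULL):
        result, _ = fit_logistic(frame, ModelSpec(adjustment_set=adj), alpha=alpha)
        out.append(result)
    return out


def _safe_fit(frame: pd.DataFrame, spec: ModelSpec, alpha: float, stratum: str) -> AssociationResult:
    from dataclasses import replace as _replace

    try:
        result, _ = fit_logistic(frame, spec, alpha=alpha)
        return _replace(result, stratum=stratum)
    except (SeparationError, ValueError) as exc:
        n_cases = int(frame["outcome"].sum()) if len(frame) else 0
        return AssociationResult(
            np.nan, np.nan, np.nan, np.nan,
            n_cases=n_cases,
            n_controls=int(len(frame) - n_cases),
            model=spec.describe(),
            stratum=stratum,
            converged=False,
            note=str(exc),
        )


def stratified_analysis(frame: pd.DataFrame, alpha: float = 0.05) -> list[AssociationResult]:
    """Prespecified strata, each with the full adjustment minus the
    stratifying variable.

    LDL-C refinement strata compare low-group patients with median < 40
    (strict) or in [40, 60] against the *whole* normal group.
    """
    results: list[AssociationResult] = []
    for level in ("female", "male"):
        sub = frame[frame["sex"] == level]
        spec = ModelSpec(
            adjustment_set=tuple(t for t in ADJUSTMENT_FULL if t != "sex"),
            stratum=("sex", level),
        )
        results.append(_safe_fit(sub, spec, alpha, f"sex={level}"))
    for level in ("european_ancestry", "african_ancestry"):
        sub = frame[frame["race"] == level]
        spec = ModelSpec(
            adjustment_set=tuple(t for t in ADJUSTMENT_FULL if t != "race"),
            stratum=("race", level),
        )
        results.append(_safe_fit(sub, spec, alpha, f"race={level}"))
    for level in ("normal", "overweight", "obese"):
        sub = frame[frame["bmi_category"] == level]
        spec = ModelSpec(
            adjustment_set=tuple(t for t in ADJUSTMENT_FULL if t != "bmi"),
            stratum=("bmi_category", level),
        )
        results.append(_safe_fit(sub, spec, alpha, f"bmi={level}"))
    for label, mask in (
        ("ldl<40", (frame["exposure"] == 1) & (frame["median_ldl"] < 40.0)),
        ("ldl40-60", (frame["exposure"] == 1) & frame["median_ldl"].between(40.0, 60.0)),
    ):
        sub = frame[mask | (frame["exposure"] == 0)]
        spec = ModelSpec(adjustment_set=ADJUSTMENT_FULL, stratum=("ldl_refinement", label))
        results.append(_safe_fit(sub, spec, alpha, f"ldl={label}"))
    return results


def interaction_test(
    frame: pd.DataFrame, variable: str, alpha: float = 0.05
) -> tuple[float, AssociationResult]:
    """Wald test on exposure×variable product term(s) added to the fully
    adjusted model; returns (p-value, main-exposure result)."""
    if variable not in ("sex", "race", "bmi_category"):
        raise ValueError(f"interaction variable must be sex, race or bmi_category, got {variable!r}")
    col = {"sex": "sex", "race": "race", "bmi_category": "bmi_category"}[variable]
    if frame[col].nunique() < 2:
        raise ValueError(f"interaction variable {variable!r} has a single level in these data")
    spec = ModelSpec(adjustment_set=ADJUSTMENT_FULL, interaction_term=variable)
    result, res = fit_logistic(frame, spec, alpha=alpha)
    if not result.converged:
        return float("nan"), result
    return wald_interaction_p(res), result


def sensitivity_suite(
    frame: pd.DataFrame,
    ldl_records: pd.DataFrame,
    codes: pd.DataFrame,
    labs: pd.DataFrame,
    medications: pd.DataFrame,
    patients: pd.DataFrame,
    phecode_map: PhecodeMap,
    config: RunConfig | None = None,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Re-fit the fully adjusted primary model under each restriction.

    (1) ≥2 eligible LDL-C measurements; (2a) no diabetes (250.*) or
    ischemic-heart-disease (411.*) phecode up to 30 days after the first
    qualified LDL-C measurement; (2b) additionally no advanced renal
    disease (phecodes 585.31/585.32/585.34 or eGFR ≤ 29 ml/min) or organ
    transplant codes in that window; (2c) additionally no stroke/TIA/PVD
    codes in that window; (3) no ezetimibe mention ever; (4) age ≥ 18 at
    the median-LDL date. Restrictions 2a–2c nest by construction.
    """
    config = config or RunConfig()
    spec = ModelSpec(adjustment_set=ADJUSTMENT_FULL)

    elig = ldl_records[~ldl_records["excluded"]]
    n_ldl = elig.groupby("patient_id").size()
    first_ldl = elig.groupby("patient_id")["date"].min().rename("first_ldl_date")
    window = pd.Timedelta(days=30)

    work = frame.merge(first_ldl, on="patient_id", how="left")

    # phecode of each coded event, for prefix-based condition groups
    coded = codes.merge(first_ldl, on="patient_id", how="inner")
    coded = coded[coded["date"] <= coded["first_ldl_date"] + window]
    phemap = coded["icd9"].map(lambda c: phecode_map.phecodes_for(c))
    coded = coded.assign(phecodes=phemap)

    def _patients_with(pred) -> set:
        if coded.empty:
            return set()
        hit = coded[coded.apply(pred, axis=1)]
        return set(hit["patient_id"])

    statin_indication = _patients_with(
        lambda r: any(p.startswith("250") or p.startswith("411") for p in r["phecodes"])
    )
    renal_code = _patients_with(lambda r: any(p in RENAL_PHECODES for p in r["phecodes"]))
    transplant = _patients_with(lambda r: r["icd9"] in TRANSPLANT_ICD9)
    stroke_list = (
        STROKE_ICD9_SUBSTITUTED if config.substitute_4339x_for_3349 else STROKE_ICD9
    )
    stroke = _patients_with(lambda r: r["icd9"] in stroke_list)

    egfr = labs[(labs["lab_type"] == "egfr") & (labs["value"] <= EGFR_THRESHOLD)]
    egfr = egfr.merge(first_ldl, on="patient_id", how="inner")
    low_egfr = set(egfr.loc[egfr["date"] <= egfr["first_ldl_date"] + window, "patient_id"])

    ezetimibe = (
        set(medications.loc[medications["drug_class"] == "ezetimibe", "patient_id"])
        if len(medications)
        else set()
    )

    birth = patients.set_index("patient_id")["birth_date"]
    age_at_median = (
        pd.to_datetime(work["median_ldl_date"]) - work["patient_id"].map(birth)
    ).dt.days / 365.25

    drop_2a = statin_indication
    drop_2b = drop_2a | renal_code | low_egfr | transplant
    drop_2c = drop_2b | stroke

    filters: list[tuple[str, pd.Series]] = [
        ("sens1_min2_ldl", work["patient_id"].map(n_ldl).fillna(0) >= 2),
        ("sens2a_no_statin_indication", ~work["patient_id"].isin(drop_2a)),
        ("sens2b_also_no_renal_transplant", ~work["patient_id"].isin(drop_2b)),
        ("sens2c_also_no_stroke_pvd", ~work["patient_id"].isin(drop_2c)),
        ("sens3_no_ezetimibe", ~work["patient_id"].isin(ezetimibe)),
        ("sens4_adults_only", age_at_median >= 18.0),
    ]
    results = []
    for label, keep in filters:
        sub = work[keep.to_numpy()]
        logger.info("sensitivity %s: %d of %d rows retained", label, len(sub), len(work))
        results.append(_safe_fit(sub, spec, alpha, label))
    return results
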