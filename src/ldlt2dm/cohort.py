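"""LDL-C cohort construction.

Implements the eligibility flowchart: per-measurement filtering, Friedewald
LDL-C derivation, median-based low/normal group assignment, and the seeded
1/3–2/3 discovery/validation split.

A candidate LDL-C determination is any date on which a patient has either a
complete lipid panel (total cholesterol, HDL-C and triglycerides) or a
direct LDL-C result; a direct result overrides the Friedewald value on the
same date. Measurements are excluded — with the *first* matching reason
recorded, in a fixed precedence order — when they were taken as an
inpatient, before age 5, within ±30 days of a serum albumin < 3 g/dl,
after the first statin mention, or (optionally) when triglycerides exceed
400 mg/dl and the value is Friedewald-derived.

Group definitions over the surviving per-patient values:

* low:     median ≤ 60 mg/dl and no measurement ever ≥ 80 mg/dl
* normal:  median in [90, 130] mg/dl and no measurement ever ≥ 150 or ≤ 80
* everyone else is excluded with a named reason (gap median, negative
  median from the Friedewald artefact, out-of-band readings, or no
  eligible measurement at all).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "friedewald_ldl",
    "filter_ldl_measurements",
    "assign_groups",
    "split_phases",
    "attrition_report",
]

logger = logging.getLogger(__name__)

EXCLUSION_PRECEDENCE = ["inpatient", "age_under_5", "low_albumin_window", "post_statin", "tg_over_400"]

LDL_RECORD_COLUMNS = [
    "patient_id",
    "date",
    "ldl_value",
    "source",
    "triglycerides",
    "excluded",
    "exclusion_reason",
]

COHORT_COLUMNS = [
    "patient_id",
    "median_ldl",
    "max_ldl",
    "min_ldl",
    "n_ldl",
    "group",
    "exclusion_reason",
    "phase",
    "median_ldl_date",
]


def friedewald_ldl(total_cholesterol, hdl_c, triglycerides):
    """LDL-C (mg/dl) by the Friedewald formula: TC − HDL − TG/5.

    Accepts scalars or arrays; the result may legitimately be negative at
    very low cholesterol (an artefact of the formula that the cohort rules
    handle downstream). Validity at high triglycerides is the caller's
    concern (see the ``tg_over_400`` filter).
    """
    tc = np.asarray(total_cholesterol, dtype=float)
    hdl = np.asarray(hdl_c, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    if not (np.all(np.isfinite(tc)) and np.all(np.isfinite(hdl)) and np.all(np.isfinite(tg))):
        raise ValueError("friedewald_ldl: inputs must be finite")
    if np.any(tc < 0) or np.any(hdl < 0) or np.any(tg < 0):
        raise ValueError("friedewald_ldl: lipid inputs must be non-negative")
    out = tc - hdl - tg / 5.0
    return float(out) if out.ndim == 0 else out


def filter_ldl_measurements(
    labs: pd.DataFrame,
    codes: pd.DataFrame,
    medications: pd.DataFrame,
    patients: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """One row per candidate LDL-C determination with its exclusion status.

    Determinations missing Friedewald components (and without a direct
    value) are skipped with a logged count. ``codes`` is accepted for
    signature symmetry with the other table-level operations; no code-based
    rule applies at this stage.
    """
    del codes  # measurement-level exclusions use labs, meds and demographics only
    config = config or RunConfig()
    if labs.empty:
        return pd.DataFrame(columns=LDL_RECORD_COLUMNS)
    lip = labs[labs["lab_type"].isin(["total_cholesterol", "hdl_c", "triglycerides", "ldl_c_direct"])]
    wide = (
        lip.pivot_table(
            index=["patient_id", "date"],
            columns="lab_type",
            values="value",
            aggfunc="first",
        )
        .reindex(columns=["total_cholesterol", "hdl_c", "triglycerides", "ldl_c_direct"])
        .reset_index()
    )
    inp = (
        lip.groupby(["patient_id", "date"])["inpatient"].any().rename("inpatient").reset_index()
    )
    wide = wide.merge(inp, on=["patient_id", "date"])

    has_panel = wide[["total_cholesterol", "hdl_c", "triglycerides"]].notna().all(axis=1)
    has_direct = wide["ldl_c_direct"].notna()
    skipped = int((~has_panel & ~has_direct).sum())
    if skipped:
        logger.info("filter_ldl_measurements: skipped %d incomplete determinations", skipped)
    wide = wide[has_panel | has_direct].copy()
    if wide.empty:
        return pd.DataFrame(columns=LDL_RECORD_COLUMNS)

    fried = np.where(
        wide[["total_cholesterol", "hdl_c", "triglycerides"]].notna().all(axis=1),
        wide["total_cholesterol"].to_numpy(dtype=float)
        - wide["hdl_c"].to_numpy(dtype=float)
        - wide["triglycerides"].to_numpy(dtype=float) / 5.0,
        np.nan,
    )
    direct = wide["ldl_c_direct"].to_numpy(dtype=float)
    wide["ldl_value"] = np.where(np.isfinite(direct), direct, fried)
    wide["source"] = np.where(np.isfinite(direct), "direct", "friedewald")

    wide = wide.merge(patients[["patient_id", "birth_date"]], on="patient_id", how="left")

    # exclusion flags, applied in fixed precedence order
    age5 = wide["date"] < wide["birth_date"] + pd.DateOffset(years=5)

    alb = labs[(labs["lab_type"] == "albumin") & (labs["value"] < config.albumin_threshold)]
    if alb.empty:
        near_alb = pd.Series(False, index=wide.index)
    else:
        joined = wide[["patient_id", "date"]].reset_index().merge(
            alb[["patient_id", "date"]].rename(columns={"date": "alb_date"}), on="patient_id"
        )
        window = pd.Timedelta(days=config.albumin_window_days)
        joined = joined[(joined["date"] - joined["alb_date"]).abs() <= window]
        near_alb = pd.Series(False, index=wide.index)
        near_alb.loc[joined["index"].unique()] = True

    statins = medications[medications["drug_class"] == "statin"] if len(medications) else medications
    if len(statins):
        first_statin = statins.groupby("patient_id")["date"].min().rename("first_statin")
        wide = wide.merge(first_statin, on="patient_id", how="left")
        post_statin = wide["date"] >= wide["first_statin"]
        post_statin = post_statin.fillna(False)
    else:
        post_statin = pd.Series(False, index=wide.index)

    tg_high = (
        (wide["source"] == "friedewald")
        & (wide["triglycerides"] > 400.0)
        if config.tg_over_400_filter
        else pd.Series(False, index=wide.index)
    )

    reason = np.full(len(wide), "none", dtype=object)
    for name, mask in [
        ("tg_over_400", tg_high),
        ("post_statin", post_statin),
        ("low_albumin_window", near_alb),
        ("age_under_5", age5),
        ("inpatient", wide["inpatient"].astype(bool)),
    ]:
        # later assignments win → apply in reverse precedence
        reason[np.asarray(mask, dtype=bool)] = name

    out = wide[["patient_id", "date", "ldl_value", "source", "triglycerides"]].copy()
    out["excluded"] = reason != "none"
    out["exclusion_reason"] = reason
    return out.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)


def assign_groups(ldl_records: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-patient group assignment over non-excluded LDL records.

    The median of an even count is the mean of the two central values.
    ``median_ldl_date`` is the date of the eligible measurement whose value
    lies closest to the median (earliest date on ties) — the anchor for the
    age-at-median sensitivity filter.
    """
    config = config or RunConfig()
    if ldl_records.empty:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    elig = ldl_records[~ldl_records["excluded"]]
    stats = elig.groupby("patient_id")["ldl_value"].agg(
        median_ldl="median", max_ldl="max", min_ldl="min", n_ldl="count"
    )
    all_ids = ldl_records["patient_id"].unique()
    stats = stats.reindex(sorted(all_ids))

    med = stats["median_ldl"]
    group = np.full(len(stats), "excluded", dtype=object)
    reason = np.full(len(stats), "none", dtype=object)

    no_elig = med.isna().to_numpy()
    negative = (~no_elig) & (med < 0).to_numpy()
    low_med = (~no_elig) & (~negative) & (med <= config.low_median_max).to_numpy()
    low_ok = low_med & (stats["max_ldl"] < config.low_reading_max).to_numpy()
    gap = (
        (~no_elig)
        & (~negative)
        & (med > config.low_median_max).to_numpy()
        & (med < config.normal_median_min).to_numpy()
    )
    norm_med = (
        (~no_elig)
        & (~negative)
        & (med >= config.normal_median_min).to_numpy()
        & (med <= config.normal_median_max).to_numpy()
    )
    norm_ok = (
        norm_med
        & (stats["max_ldl"] < config.normal_reading_max).to_numpy()
        & (stats["min_ldl"] > config.low_reading_max).to_numpy()
    )
    high_med = (~no_elig) & (~negative) & (med > config.normal_median_max).to_numpy()

    reason[no_elig] = "no_eligible_ldl"
    reason[negative] = "negative_median"
    reason[low_med & ~low_ok] = "low_with_high_reading"
    reason[gap] = "median_in_gap"
    reason[(norm_med & ~norm_ok) | high_med] = "normal_out_of_band"
    group[low_ok] = "low"
    group[norm_ok] = "normal"

    out = stats.reset_index()
    out["group"] = group
    out["exclusion_reason"] = reason
    out["phase"] = ""
    out["n_ldl"] = out["n_ldl"].fillna(0).astype(int)

    # date of the eligible value closest to the median, earliest on tie
    e = elig.merge(out[["patient_id", "median_ldl"]], on="patient_id")
    e["dist"] = (e["ldl_value"] - e["median_ldl"]).abs()
    e = e.sort_values(["patient_id", "dist", "date"], kind="mergesort")
    med_date = e.groupby("patient_id").first()["date"].rename("median_ldl_date")
    out = out.merge(med_date, on="patient_id", how="left")
    return out[COHORT_COLUMNS]


def split_phases(assignments: pd.DataFrame, seed: int, discovery_fraction: float = 1.0 / 3.0) -> pd.DataFrame:
    """Seeded random split of the included patients into discovery/validation.

    The split is a uniform shuffle over the union of both LDL groups; the
    first ``⌊N·fraction⌋`` shuffled patients form the discovery phase.
    Excluded patients keep an empty phase label.
    """
    if assignments.empty:
        raise ValueError("split_phases: empty assignments")
    out = assignments.copy()
    included = np.sort(out.loc[out["group"].isin(["low", "normal"]), "patient_id"].to_numpy())
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(included)
    n_disc = int(len(shuffled) * discovery_fraction)
    disc = set(shuffled[:n_disc])
    phase = np.where(
        out["group"].isin(["low", "normal"]),
        np.where(out["patient_id"].isin(disc), "discovery", "validation"),
        "",
    )
    out["phase"] = phase
    return out


def attrition_report(ldl_records: pd.DataFrame, cohort: pd.DataFrame) -> dict:
    """Flowchart-style counts: measurement-level and patient-level attrition."""
    rec_counts = (
        ldl_records["exclusion_reason"].value_counts().to_dict() if len(ldl_records) else {}
    )
    pat_counts = cohort["exclusion_reason"].value_counts().to_dict() if len(cohort) else {}
    groups = cohort["group"].value_counts().to_dict() if len(cohort) else {}
    phases = (
        cohort.loc[cohort["phase"] != "", "phase"].value_counts().to_dict() if len(cohort) else {}
    )
    return {
        "n_ldl_measurements": int(len(ldl_records)),
        "measurement_exclusions": {k: int(v) for k, v in sorted(rec_counts.items())},
        "n_patients_with_ldl": int(cohort["patient_id"].nunique()) if len(cohort) else 0,
        "patient_exclusions": {k: int(v) for k, v in sorted(pat_counts.items())},
        "groups": {k: int(v) for k, v in sorted(groups.items())},
        "phases": {k: int(v) for k, v in sorted(phases.items())},
    }
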