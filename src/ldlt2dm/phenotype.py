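"""Case/control/excluded phenotype assignment and covariate derivation.

Two phenotyping strategies mirror the two study phases:

* **Phecode rule** (discovery): a patient is a *case* for a phecode when
  mapped ICD-9 codes appear on 2 or more distinct calendar days, *excluded*
  when exactly one such day exists (a single code is weak evidence either
  way) or when their only related codes fall inside the phecode's
  exclusion ranges, and a *control* otherwise.
* **Algorithmic T2DM classifier** (validation): a high-specificity rule
  combining type 2 diagnosis codes, diabetes medications and glycemic labs
  that abstains ("excluded") when a patient cannot be classified — e.g.
  no blood glucose was ever measured. Thresholds follow ADA conventions:
  abnormal glucose ≥ 126 mg/dl or HbA1c ≥ 6.5%; normal glucose < 100 mg/dl.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .phecodes import PhecodeMap

__all__ = [
    "assign_phecode_status",
    "t2dm_algorithm",
    "derive_covariates",
    "ABNORMAL_GLUCOSE_MGDL",
    "NORMAL_GLUCOSE_MGDL",
    "ABNORMAL_HBA1C_PCT",
]

logger = logging.getLogger(__name__)

ABNORMAL_GLUCOSE_MGDL = 126.0
NORMAL_GLUCOSE_MGDL = 100.0
ABNORMAL_HBA1C_PCT = 6.5

# ICD-9 250.x0 / 250.x2 denote type 2 or unspecified; 250.x1 / 250.x3 type 1
_T2_CODE = re.compile(r"^250\.\d[02]$")
_T1_CODE = re.compile(r"^250\.\d[13]$")
_DIABETES_RANGE = re.compile(r"^250(\.\d{1,2})?$")


def _patient_universe(patient_ids, *frames) -> pd.Index:
    if patient_ids is not None:
        return pd.Index(sorted(set(patient_ids)))
    ids: set = set()
    for f in frames:
        if f is not None and len(f):
            ids.update(f["patient_id"])
    return pd.Index(sorted(ids))


def assign_phecode_status(
    codes: pd.DataFrame,
    phecode_map: PhecodeMap,
    phenotype_id: str,
    patient_ids=None,
) -> pd.DataFrame:
    """Case/control/excluded trichotomy for one phecode over all patients.

    ``patient_ids`` fixes the universe (patients with no codes at all
    become controls); when omitted, the universe is everyone appearing in
    ``codes``. Distinct-day counting uses calendar dates.
    """
    if not phecode_map.contains(phenotype_id):
        raise KeyError(f"unknown phenotype_id {phenotype_id!r}: not in phecode map")
    universe = _patient_universe(patient_ids, codes)
    target_codes = phecode_map.icd9_for(phenotype_id, include_descendants=True)

    if len(codes):
        hits = codes[codes["icd9"].isin(target_codes)]
        n_days = hits.groupby("patient_id")["date"].nunique()
        excl_codes = {
            c
            for c in codes["icd9"].unique()
            if phecode_map.in_exclusion_range(phenotype_id, c)
        }
        in_excl = codes[codes["icd9"].isin(excl_codes)].groupby("patient_id").size()
    else:
        n_days = pd.Series(dtype=int)
        in_excl = pd.Series(dtype=int)

    n_days = n_days.reindex(universe, fill_value=0)
    has_excl = in_excl.reindex(universe, fill_value=0) > 0

    status = np.where(
        n_days >= 2,
        "case",
        np.where((n_days == 1) | has_excl, "excluded", "control"),
    )
    return pd.DataFrame(
        {
            "patient_id": universe,
            "phenotype_id": phenotype_id,
            "status": status,
            "n_code_days": n_days.to_numpy(),
        }
    ).reset_index(drop=True)


def t2dm_algorithm(
    codes: pd.DataFrame,
    labs: pd.DataFrame,
    medications: pd.DataFrame,
    patient_ids=None,
) -> pd.DataFrame:
    """High-specificity algorithmic type 2 diabetes classification.

    Case: ≥1 type 2 diagnosis code AND supporting evidence (a diabetes
    medication, glucose ≥ 126 mg/dl, or HbA1c ≥ 6.5%) AND not a
    type-1-only pattern (exclusively type 1 codes with insulin and no oral
    agent). Control: no diabetes-range codes, no diabetes medications, and
    ≥1 normal glucose < 100 mg/dl. Everyone else is excluded
    (unclassifiable) — abstention is a status, not an error.
    """
    universe = _patient_universe(patient_ids, codes, labs, medications)

    def _flag(frame, mask) -> pd.Series:
        if frame is None or not len(frame):
            return pd.Series(False, index=universe)
        s = frame.loc[mask].groupby("patient_id").size() > 0
        return s.reindex(universe, fill_value=False)

    if len(codes):
        is_t2 = codes["icd9"].str.match(_T2_CODE)
        is_t1 = codes["icd9"].str.match(_T1_CODE)
        is_dm = codes["icd9"].str.match(_DIABETES_RANGE)
    else:
        is_t2 = is_t1 = is_dm = pd.Series(dtype=bool)
    has_t2_code = _flag(codes, is_t2)
    has_t1_code = _flag(codes, is_t1)
    has_dm_code = _flag(codes, is_dm)

    glucose = labs[labs["lab_type"] == "glucose"] if len(labs) else labs
    has_abn_glucose = _flag(labs, (labs["lab_type"] == "glucose") & (labs["value"] >= ABNORMAL_GLUCOSE_MGDL)) if len(labs) else pd.Series(False, index=universe)
    has_norm_glucose = _flag(labs, (labs["lab_type"] == "glucose") & (labs["value"] < NORMAL_GLUCOSE_MGDL)) if len(labs) else pd.Series(False, index=universe)
    has_abn_hba1c = _flag(labs, (labs["lab_type"] == "hba1c") & (labs["value"] >= ABNORMAL_HBA1C_PCT)) if len(labs) else pd.Series(False, index=universe)

    has_oral = _flag(medications, medications["drug_class"] == "oral_t2dm_agent") if len(medications) else pd.Series(False, index=universe)
    has_insulin = _flag(medications, medications["drug_class"] == "insulin") if len(medications) else pd.Series(False, index=universe)

    supporting = has_oral | has_insulin | has_abn_glucose | has_abn_hba1c
    type1_only = has_t1_code & ~has_t2_code & has_insulin & ~has_oral
    case = has_t2_code & supporting & ~type1_only
    control = ~has_dm_code & ~has_oral & ~has_insulin & has_norm_glucose

    status = np.where(case, "case", np.where(control, "control", "excluded"))
    n_glucose = (
        glucose.groupby("patient_id").size().reindex(universe, fill_value=0)
        if len(glucose)
        else pd.Series(0, index=universe)
    )
    return pd.DataFrame(
        {
            "patient_id": universe,
            "phenotype_id": "t2dm_algorithm",
            "status": status,
            "n_glucose_labs": n_glucose.to_numpy(),
        }
    ).reset_index(drop=True)


def derive_covariates(
    patients: pd.DataFrame, labs: pd.DataFrame, codes: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient analysis covariates.

    Age is taken at the most recent ICD-9 code assignment (null, with a
    logged count, for patients with no codes); BMI, HDL-C and triglyceride
    covariates are medians over all available values; EHR length is the
    span in years between the first and last recorded event (labs or
    codes).
    """
    out = patients[["patient_id", "birth_date", "sex", "race"]].copy()

    if len(codes):
        last_code = codes.groupby("patient_id")["date"].max().rename("last_code_date")
        out = out.merge(last_code, on="patient_id", how="left")
        out["age_years"] = (out["last_code_date"] - out["birth_date"]).dt.days / 365.25
    else:
        out["last_code_date"] = pd.NaT
        out["age_years"] = np.nan
    n_no_codes = int(out["age_years"].isna().sum())
    if n_no_codes:
        logger.warning("derive_covariates: %d patients without ICD-9 codes (null age)", n_no_codes)

    med_map = {"bmi": "bmi_median", "hdl_c": "hdl_median", "triglycerides": "tg_median"}
    if len(labs):
        med = (
            labs[labs["lab_type"].isin(med_map)]
            .groupby(["patient_id", "lab_type"])["value"]
            .median()
            .unstack()
            .rename(columns=med_map)
        )
        out = out.merge(med, on="patient_id", how="left")
    for col in med_map.values():
        if col not in out.columns:
            out[col] = np.nan

    spans = []
    for frame in (labs, codes):
        if frame is not None and len(frame):
            g = frame.groupby("patient_id")["date"]
            spans.append(pd.DataFrame({"first": g.min(), "last": g.max()}))
    if spans:
        ev = pd.concat(spans)
        ev = ev.groupby(level=0).agg(first=("first", "min"), last=("last", "max"))
        ev["ehr_length_years"] = (ev["last"] - ev["first"]).dt.days / 365.25
        out = out.merge(ev[["ehr_length_years"]], on="patient_id", how="left")
    else:
        out["ehr_length_years"] = np.nan

    return out[
        [
            "patient_id",
            "age_years",
            "sex",
            "race",
            "bmi_median",
            "hdl_median",
            "tg_median",
            "ehr_length_years",
        ]
    ]
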