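"""Synthetic longitudinal EHR generator.

Emulates a de-identified hospital record system at the level the LDL-C →
type 2 diabetes analysis consumes: four relational tables (patients, dated
laboratory values, dated ICD-9 code events, dated medication mentions).

Key modelling choices
---------------------
* Lipid panels are generated as total cholesterol = latent LDL + HDL +
  TG/5, so the pipeline must *derive* LDL-C by the Friedewald formula; the
  latent per-patient LDL medians are log-normal, calibrated so the derived
  group medians land near 52 mg/dl (low) and 109 mg/dl (normal).
* Type 2 diabetes is a latent Bernoulli draw whose log-odds are
  ``baseline + true_log_or_low_ldl·1[low group] + Σ covariate effects``;
  affected patients then receive ≥2 type-2 ICD-9 codes on distinct days,
  an abnormal glucose, and usually a diabetes medication, so the
  downstream classifier recovers the latent status.
* Contamination pathways (statin mentions, inpatient panels, albumin
  < 3 g/dl near a panel, panels before age 5) are independent Bernoulli
  marks at configurable rates so that every cohort filter sees work.

Identical ``SimulationConfig`` (including seed) yields byte-identical
tables: all draws come from one ``numpy`` generator and outputs are sorted
on stable keys.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = ["EhrTables", "generate_population", "summarize_population", "write_tables"]

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "race"]
LAB_COLUMNS = ["patient_id", "date", "lab_type", "value", "inpatient"]
CODE_COLUMNS = ["patient_id", "date", "icd9"]
MED_COLUMNS = ["patient_id", "date", "drug_class", "drug_name"]

# ICD-9 fifth digit 0/2 = type 2 or unspecified; 1/3 = type 1.
_T2DM_PRIMARY = np.array(["250.00", "250.02"])
_T2DM_COMPLICATION = np.array(
    ["250.12", "250.40", "250.42", "250.50", "250.52", "250.60", "250.62", "250.70", "250.72"]
)
_GENERIC_CODES = np.array(["401.1", "780.79", "786.50", "786.2", "V70.0"])
_CVD_CODES = np.array(["410.90", "410.00", "411.1", "413.9"])
_RENAL_CODES = np.array(["585.3", "585.4", "585.6"])
_TRANSPLANT_CODES = np.array(["V42.0", "V42.1", "V42.2", "V42.5", "V42.6", "V42.7", "V42.81", "V42.82"])
_STROKE_CODES = np.array(["434.91", "435.9", "435.8", "334.9"])
_STATIN_NAMES = np.array(["atorvastatin", "simvastatin", "rosuvastatin", "pravastatin"])

_DAY = np.timedelta64(1, "D")


class EhrTables(NamedTuple):
    """The four relational tables plus, optionally, the generator's truth."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    codes: pd.DataFrame
    meds: pd.DataFrame
    truth: pd.DataFrame | None = None


def _empty_tables() -> EhrTables:
    return EhrTables(
        pd.DataFrame(columns=PATIENT_COLUMNS),
        pd.DataFrame(columns=LAB_COLUMNS),
        pd.DataFrame(columns=CODE_COLUMNS),
        pd.DataFrame(columns=MED_COLUMNS),
        pd.DataFrame(columns=["patient_id", "ldl_group", "t2dm", "age_years", "bmi"]),
    )


def generate_population(config: SimulationConfig, return_truth: bool = True) -> EhrTables:
    """Generate one synthetic population under ``config``.

    Returns the four tables (dates as ``datetime64[ns]``); ``truth`` holds
    the latent group, T2DM status and covariates used to draw it, for
    parameter-recovery experiments. Set ``return_truth=False`` to omit it.
    """
    n = config.n_patients
    if n == 0:
        t = _empty_tables()
        return t if return_truth else t._replace(truth=None)
    rng = np.random.default_rng(config.seed)

    pid = np.array([f"P{i:06d}" for i in range(n)])

    # --- demographics and record window ------------------------------------
    low = rng.random(n) < config.frac_low_ldl
    sex = np.where(rng.random(n) < 0.57, "female", "male")
    race = rng.choice(
        np.array(["european_ancestry", "african_ancestry", "other"]), size=n, p=[0.69, 0.14, 0.17]
    )
    window_start = np.datetime64(config.window_start, "D")
    window_days = int(config.window_years * 365.25)
    span_days = np.clip(
        (rng.lognormal(np.log(6.8), 0.8, n) * 365.25).astype(np.int64), 60, window_days - 1
    )
    first_offset = rng.integers(0, window_days - span_days + 1)
    first_date = window_start + first_offset * _DAY
    end_date = first_date + span_days * _DAY

    # age at the end of the record; low-LDL patients skew younger (observed
    # hospital-population pattern the analysis must adjust for)
    age = np.where(
        low,
        rng.lognormal(np.log(33.0), 0.55, n),
        rng.lognormal(np.log(42.6), 0.45, n),
    )
    age = np.clip(age, 6.0, 90.0)
    # a record cannot start before the patient existed: cap the span so the
    # first event falls at least 30 days after birth
    span_days = np.minimum(span_days, (age * 365.25).astype(np.int64) - 30)
    end_date = first_date + span_days * _DAY
    birth_date = end_date - (age * 365.25).astype(np.int64) * _DAY

    # --- latent lipid and BMI levels ----------------------------------------
    # latent low-group centre sits above the observed 52 mg/dl because the
    # median<=60 / max<80 eligibility rules truncate the upper tail
    ldl_med = np.where(
        low,
        rng.lognormal(np.log(56.0), 0.16, n),
        rng.lognormal(np.log(109.0), 0.12, n),
    )
    hdl_med = rng.lognormal(np.log(51.0), 0.25, n)
    tg_med = np.where(
        low,
        rng.lognormal(np.log(88.0), 0.45, n),
        rng.lognormal(np.log(101.0), 0.40, n),
    )
    bmi_true = np.where(
        low,
        rng.lognormal(np.log(24.5), 0.20, n),
        rng.lognormal(np.log(27.1), 0.19, n),
    )

    # --- latent T2DM liability ----------------------------------------------
    eff = config.covariate_effects
    logit = (
        config.baseline_t2dm_logit
        + config.true_log_or_low_ldl * low
        + eff["age"] * (age - 45.0)
        + eff["male"] * (sex == "male")
        + eff["african_ancestry"] * (race == "african_ancestry")
        + eff["bmi"] * (bmi_true - 27.0)
    )
    t2dm = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    labs: list[pd.DataFrame] = []
    codes: list[pd.DataFrame] = []
    meds: list[pd.DataFrame] = []

    def _rand_dates(idx: np.ndarray) -> np.ndarray:
        """One uniform date inside each indexed patient's record window."""
        off = rng.integers(0, span_days[idx] + 1)
        return first_date[idx] + off * _DAY

    # --- lipid panels --------------------------------------------------------
    k = 1 + rng.poisson(config.mean_extra_panels, n)
    owner = np.repeat(np.arange(n), k)
    m = owner.size
    panel_date = _rand_dates(owner)
    ldl_v = ldl_med[owner] + rng.normal(0.0, 5.0, m)
    hdl_v = np.clip(hdl_med[owner] + rng.normal(0.0, 4.0, m), 10.0, None)
    tg_v = tg_med[owner] * rng.lognormal(0.0, 0.15, m)
    tc_v = ldl_v + hdl_v + tg_v / 5.0
    inpatient = rng.random(m) < config.frac_inpatient_panel

    def _panel_frame(idx, dates, tc, hdl, tg, inp) -> pd.DataFrame:
        rows = len(idx)
        return pd.DataFrame(
            {
                "patient_id": np.tile(pid[idx], 3),
                "date": np.tile(dates, 3),
                "lab_type": np.repeat(["total_cholesterol", "hdl_c", "triglycerides"], rows),
                "value": np.concatenate([tc, hdl, tg]),
                "inpatient": np.tile(inp, 3),
            }
        )

    labs.append(_panel_frame(owner, panel_date, tc_v, hdl_v, tg_v, inpatient))

    direct = rng.random(m) < config.frac_direct_ldl
    if direct.any():
        labs.append(
            pd.DataFrame(
                {
                    "patient_id": pid[owner[direct]],
                    "date": panel_date[direct],
                    "lab_type": "ldl_c_direct",
                    "value": ldl_v[direct] + rng.normal(0.0, 2.0, int(direct.sum())),
                    "inpatient": inpatient[direct],
                }
            )
        )

    # paediatric panels: an extra panel dated before the fifth birthday
    u5 = np.flatnonzero(rng.random(n) < config.frac_under5_panel)
    if u5.size:
        d5 = birth_date[u5] + rng.integers(2 * 365, 5 * 365, u5.size) * _DAY
        labs.append(
            _panel_frame(
                u5,
                d5,
                ldl_med[u5] + hdl_med[u5] + tg_med[u5] / 5.0,
                hdl_med[u5],
                tg_med[u5],
                np.zeros(u5.size, bool),
            )
        )

    # --- albumin, eGFR, BMI, glucose/HbA1c -----------------------------------
    labs.append(
        pd.DataFrame(
            {
                "patient_id": pid,
                "date": _rand_dates(np.arange(n)),
                "lab_type": "albumin",
                "value": rng.uniform(3.4, 4.8, n),
                "inpatient": False,
            }
        )
    )
    low_alb = np.flatnonzero(rng.random(n) < config.frac_low_albumin)
    if low_alb.size:
        # anchored near that patient's first panel so the ±30 day window bites
        first_panel = pd.Series(panel_date).groupby(owner).min()
        anchor = first_panel.reindex(low_alb).to_numpy()
        labs.append(
            pd.DataFrame(
                {
                    "patient_id": pid[low_alb],
                    "date": anchor + rng.integers(-15, 16, low_alb.size) * _DAY,
                    "lab_type": "albumin",
                    "value": rng.uniform(1.8, 2.9, low_alb.size),
                    "inpatient": False,
                }
            )
        )
    egfr = np.clip(rng.normal(90.0, 18.0, n), 15.0, 140.0)
    low_egfr = rng.random(n) < config.frac_low_egfr
    egfr[low_egfr] = rng.uniform(8.0, 29.0, int(low_egfr.sum()))
    labs.append(
        pd.DataFrame(
            {
                "patient_id": pid,
                "date": _rand_dates(np.arange(n)),
                "lab_type": "egfr",
                "value": egfr,
                "inpatient": False,
            }
        )
    )
    bmi_owner = np.repeat(np.arange(n), 3)
    labs.append(
        pd.DataFrame(
            {
                "patient_id": pid[bmi_owner],
                "date": _rand_dates(bmi_owner),
                "lab_type": "bmi",
                "value": bmi_true[bmi_owner] * rng.lognormal(0.0, 0.01, bmi_owner.size),
                "inpatient": False,
            }
        )
    )
    pos = np.flatnonzero(t2dm)
    neg = np.flatnonzero(~t2dm)
    if pos.size:
        labs.append(
            pd.DataFrame(
                {
                    "patient_id": pid[pos],
                    "date": _rand_dates(pos),
                    "lab_type": "glucose",
                    "value": rng.uniform(130.0, 240.0, pos.size),
                    "inpatient": False,
                }
            )
        )
        hba = pos[rng.random(pos.size) < 0.5]
        if hba.size:
            labs.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[hba],
                        "date": _rand_dates(hba),
                        "lab_type": "hba1c",
                        "value": rng.uniform(6.6, 9.5, hba.size),
                        "inpatient": False,
                    }
                )
            )
    if neg.size:
        labs.append(
            pd.DataFrame(
                {
                    "patient_id": pid[neg],
                    "date": _rand_dates(neg),
                    "lab_type": "glucose",
                    "value": rng.uniform(75.0, 99.0, neg.size),
                    "inpatient": False,
                }
            )
        )

    # --- ICD-9 code stream ---------------------------------------------------
    # anchors at both window ends make age-at-last-code and EHR length exact
    codes.append(pd.DataFrame({"patient_id": pid, "date": first_date, "icd9": "V70.0"}))
    codes.append(pd.DataFrame({"patient_id": pid, "date": end_date, "icd9": "401.1"}))
    kg = rng.poisson(2.0, n)
    gowner = np.repeat(np.arange(n), kg)
    if gowner.size:
        codes.append(
            pd.DataFrame(
                {
                    "patient_id": pid[gowner],
                    "date": _rand_dates(gowner),
                    "icd9": rng.choice(_GENERIC_CODES, gowner.size),
                }
            )
        )
    if pos.size:
        # two guaranteed distinct-day primary codes, then extras
        o1 = rng.integers(0, span_days[pos])
        o2 = (o1 + 1 + rng.integers(0, span_days[pos])) % (span_days[pos] + 1)
        codes.append(
            pd.DataFrame(
                {
                    "patient_id": np.tile(pid[pos], 2),
                    "date": np.concatenate([first_date[pos] + o1 * _DAY, first_date[pos] + o2 * _DAY]),
                    "icd9": rng.choice(_T2DM_PRIMARY, 2 * pos.size),
                }
            )
        )
        ke = rng.poisson(1.0, pos.size)
        eo = np.repeat(pos, ke)
        if eo.size:
            codes.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[eo],
                        "date": _rand_dates(eo),
                        "icd9": rng.choice(
                            np.concatenate([_T2DM_PRIMARY, _T2DM_COMPLICATION]), eo.size
                        ),
                    }
                )
            )

    for frac, pool in (
        (config.frac_cvd_codes, _CVD_CODES),
        (config.frac_renal_codes, _RENAL_CODES),
        (config.frac_transplant_codes, _TRANSPLANT_CODES),
        (config.frac_stroke_codes, _STROKE_CODES),
    ):
        # none of these pools contains 250.* codes, so they never
        # contradict the latent T2DM-negative contract
        sel = np.flatnonzero(rng.random(n) < frac)
        if sel.size:
            codes.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[sel],
                        "date": _rand_dates(sel),
                        "icd9": rng.choice(pool, sel.size),
                    }
                )
            )

    # --- medication mentions -------------------------------------------------
    if pos.size:
        met = pos[rng.random(pos.size) < 0.8]
        if met.size:
            meds.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[met],
                        "date": _rand_dates(met),
                        "drug_class": "oral_t2dm_agent",
                        "drug_name": "metformin",
                    }
                )
            )
        ins = pos[rng.random(pos.size) < 0.3]
        if ins.size:
            meds.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[ins],
                        "date": _rand_dates(ins),
                        "drug_class": "insulin",
                        "drug_name": "insulin glargine",
                    }
                )
            )
    statin = np.flatnonzero(rng.random(n) < config.frac_statin)
    if statin.size:
        meds.append(
            pd.DataFrame(
                {
                    "patient_id": pid[statin],
                    "date": _rand_dates(statin),
                    "drug_class": "statin",
                    "drug_name": rng.choice(_STATIN_NAMES, statin.size),
                }
            )
        )
    ez = np.flatnonzero(rng.random(n) < config.frac_ezetimibe)
    if ez.size:
        meds.append(
            pd.DataFrame(
                {
                    "patient_id": pid[ez],
                    "date": _rand_dates(ez),
                    "drug_class": "ezetimibe",
                    "drug_name": "ezetimibe",
                }
            )
        )
    other = np.flatnonzero(rng.random(n) < 0.3)
    if other.size:
        meds.append(
            pd.DataFrame(
                {
                    "patient_id": pid[other],
                    "date": _rand_dates(other),
                    "drug_class": "other",
                    "drug_name": "lisinopril",
                }
            )
        )

    patients = pd.DataFrame(
        {"patient_id": pid, "birth_date": pd.to_datetime(birth_date), "sex": sex, "race": race}
    )
    labs_df = pd.concat(labs, ignore_index=True)
    labs_df["date"] = pd.to_datetime(labs_df["date"])
    labs_df["inpatient"] = labs_df["inpatient"].astype(bool)
    labs_df = labs_df.sort_values(["patient_id", "date", "lab_type", "value"], kind="mergesort").reset_index(drop=True)
    codes_df = pd.concat(codes, ignore_index=True)
    codes_df["date"] = pd.to_datetime(codes_df["date"])
    codes_df = codes_df.sort_values(["patient_id", "date", "icd9"], kind="mergesort").reset_index(drop=True)
    meds_df = (
        pd.concat(meds, ignore_index=True)
        if meds
        else pd.DataFrame(columns=MED_COLUMNS)
    )
    if len(meds_df):
        meds_df["date"] = pd.to_datetime(meds_df["date"])
        meds_df = meds_df.sort_values(["patient_id", "date", "drug_class", "drug_name"], kind="mergesort").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "ldl_group": np.where(low, "low", "normal"),
            "t2dm": t2dm.astype(int),
            "age_years": age,
            "bmi": bmi_true,
        }
    )
    logger.info(
        "generated %d patients (%d low LDL, %d T2DM), %d labs, %d codes, %d meds",
        n, int(low.sum()), int(t2dm.sum()), len(labs_df), len(codes_df), len(meds_df),
    )
    return EhrTables(patients, labs_df, codes_df, meds_df, truth if return_truth else None)


def _median_iqr(values: pd.Series) -> str:
    v = values.dropna()
    if v.empty:
        return ""
    return f"{v.median():.1f} ({v.quantile(0.25):.1f}-{v.quantile(0.75):.1f})"


def summarize_population(
    cohort: pd.DataFrame, covariates: pd.DataFrame, patients: pd.DataFrame
) -> pd.DataFrame:
    """Demographic summary per LDL group: N (%) or median (IQR) per row.

    ``cohort`` must carry ``patient_id``, ``group`` and ``median_ldl``;
    ``covariates`` the per-patient medians and EHR length. Groups with zero
    members yield null rows with a logged warning.
    """
    if cohort.empty:
        raise ValueError("summarize_population: empty cohort")
    df = cohort[cohort["group"].isin(["low", "normal"])].merge(
        covariates, on="patient_id", how="left"
    )
    if "sex" not in df.columns:
        df = df.merge(patients[["patient_id", "sex", "race"]], on="patient_id", how="left")
    rows = []
    for group in ("low", "normal"):
        g = df[df["group"] == group]
        if g.empty:
            logger.warning("summarize_population: group %r has no members", group)
            rows.append({"group": group, "n": 0})
            continue
        row = {
            "group": group,
            "n": len(g),
            "female_n_pct": f"{(g['sex'] == 'female').sum()} ({(g['sex'] == 'female').mean() * 100:.1f}%)",
            "european_ancestry_n_pct": f"{(g['race'] == 'european_ancestry').sum()} ({(g['race'] == 'european_ancestry').mean() * 100:.1f}%)",
            "african_ancestry_n_pct": f"{(g['race'] == 'african_ancestry').sum()} ({(g['race'] == 'african_ancestry').mean() * 100:.1f}%)",
            "ldl_median_iqr": _median_iqr(g["median_ldl"]),
            "hdl_median_iqr": _median_iqr(g["hdl_median"]),
            "tg_median_iqr": _median_iqr(g["tg_median"]),
            "bmi_median_iqr": _median_iqr(g["bmi_median"]),
            "age_median_iqr": _median_iqr(g["age_years"]),
            "ehr_length_median_iqr": _median_iqr(g["ehr_length_years"]),
            "median_ldl": float(g["median_ldl"].median()),
            "median_age": float(g["age_years"].median()),
            "median_ehr_length": float(g["ehr_length_years"].median()),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_tables(tables: EhrTables, out_dir, header_comment: str | None = None) -> dict[str, str]:
    """Write the four tables as UTF-8 CSVs with ISO-8601 dates."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = {"patients": "patients.csv", "labs": "labs.csv", "codes": "codes.csv", "meds": "meds.csv"}
    written = {}
    for attr, fname in names.items():
        df = getattr(tables, attr)
        path = out / fname
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False, date_format="%Y-%m-%d")
        written[attr] = str(path)
    return written
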