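import numpy as np
import pandas as pd
import pytest

from ldlt2dm import RunConfig, SimulationConfig, generate_population


def make_labs(rows):
    """rows: (patient_id, date, lab_type, value[, inpatient])"""
    recs = []
    for r in rows:
        pid, date, lab_type, value = r[:4]
        inpatient = r[4] if len(r) > 4 else False
        recs.append(
            {
                "patient_id": pid,
                "date": pd.Timestamp(date),
                "lab_type": lab_type,
                "value": float(value),
                "inpatient": bool(inpatient),
            }
        )
    return pd.DataFrame(recs)


def make_panel(pid, date, ldl, hdl=50.0, tg=100.0, inpatient=False):
    """A lipid panel whose Friedewald LDL-C equals ``ldl`` exactly."""
    tc = ldl + hdl + tg / 5.0
    return make_labs(
        [
            (pid, date, "total_cholesterol", tc, inpatient),
            (pid, date, "hdl_c", hdl, inpatient),
            (pid, date, "triglycerides", tg, inpatient),
        ]
    )


def make_codes(rows):
    return pd.DataFrame(
        [{"patient_id": p, "date": pd.Timestamp(d), "icd9": c} for p, d, c in rows],
        columns=["patient_id", "date", "icd9"],
    )


def make_meds(rows):
    return pd.DataFrame(
        [
            {"patient_id": p, "date": pd.Timestamp(d), "drug_class": cls, "drug_name": name}
            for p, d, cls, name in rows
        ],
        columns=["patient_id", "date", "drug_class", "drug_name"],
    )


def make_patients(rows):
    """rows: (patient_id, birth_date[, sex[, race]])"""
    recs = []
    for r in rows:
        recs.append(
            {
                "patient_id": r[0],
                "birth_date": pd.Timestamp(r[1]),
                "sex": r[2] if len(r) > 2 else "female",
                "race": r[3] if len(r) > 3 else "european_ancestry",
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def default_run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_population():
    """A 2,000-patient simulated population shared across read-only tests."""
    return generate_population(SimulationConfig(n_patients=2000, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260901)
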