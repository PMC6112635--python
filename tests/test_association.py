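"""Odds-ratio estimation, the discovery screen, strata, interactions and
sensitivity filters."""

import math

import numpy as np
import pandas as pd
import pytest

from ldlt2dm import (
    ContingencyTable2x2,
    ModelSpec,
    PhecodeMap,
    RunConfig,
    SeparationError,
    expand_table,
    fit_logistic,
    odds_ratio_woolf,
)
from ldlt2dm.association import (
    bmi_category,
    build_analysis_frame,
    interaction_test,
    sensitivity_suite,
    stratified_analysis,
)
from ldlt2dm.stats import ADJUSTMENT_FULL

from conftest import make_codes, make_labs, make_meds, make_patients

VALIDATION_TABLE = ContingencyTable2x2(a=518, b=2896, c=2968, d=26657)


def woolf_oracle(a, b, c, d, z=1.959963984540054):
    """Independent closed-form recomputation (plain math, no package code)."""
    lo = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(lo), math.exp(lo - z * se), math.exp(lo + z * se)


def test_woolf_matches_independent_closed_form():
    res = odds_ratio_woolf(ContingencyTable2x2(5, 5, 5, 5))
    or_, lo, hi = woolf_oracle(5, 5, 5, 5)
    assert res.or_estimate == pytest.approx(or_, abs=1e-12)
    assert res.ci_low == pytest.approx(lo, abs=1e-12)
    assert res.ci_high == pytest.approx(hi, abs=1e-12)


def test_balanced_table_is_symmetric_about_one():
    res = odds_ratio_woolf(ContingencyTable2x2(10, 10, 10, 10))
    assert res.or_estimate == pytest.approx(1.0)
    assert res.ci_low * res.ci_high == pytest.approx(1.0)  # log-symmetric
    assert res.p_value == pytest.approx(1.0)


def test_zero_cell_raises_and_continuity_correction_rescues():
    with pytest.raises(ValueError, match="continuity"):
        odds_ratio_woolf(ContingencyTable2x2(0, 10, 10, 10))
    res = odds_ratio_woolf(ContingencyTable2x2(0, 10, 10, 10), continuity_correction=True)
    assert np.isfinite(res.or_estimate)


def test_logistic_equals_cross_product_on_single_predictor():
    """Analytic identity: one binary predictor → logistic OR == ad/bc."""
    rows = expand_table(VALIDATION_TABLE)
    woolf = odds_ratio_woolf(VALIDATION_TABLE)
    fit, _ = fit_logistic(rows, ModelSpec(adjustment_set=()))
    assert fit.or_estimate == pytest.approx(woolf.or_estimate, abs=1e-6)
    assert fit.ci_low == pytest.approx(woolf.ci_low, abs=1e-6)
    assert fit.ci_high == pytest.approx(woolf.ci_high, abs=1e-6)


def test_degenerate_outcome_raises_separation_error():
    rows = expand_table(ContingencyTable2x2(0, 20, 0, 20))
    rows["outcome"] = 0
    with pytest.raises(SeparationError):
        fit_logistic(rows, ModelSpec(adjustment_set=()))


def test_perfectly_separated_covariate_flagged_not_silent():
    rng = np.random.default_rng(0)
    n = 200
    df = pd.DataFrame(
        {
            "exposure": rng.integers(0, 2, n),
            "age_years": rng.uniform(20, 80, n),
        }
    )
    df["outcome"] = (df["age_years"] > 50).astype(int)  # separation on age
    result, _ = fit_logistic(df, ModelSpec(adjustment_set=("age",)))
    assert not result.converged
    assert result.note != ""
    assert np.isnan(result.or_estimate)


def test_model_spec_rejects_stratum_in_adjustment_set():
    with pytest.raises(ValueError):
        ModelSpec(adjustment_set=("age", "sex"), stratum=("sex", "male"))


def test_bmi_category_boundaries():
    cats = bmi_category(pd.Series([17.0, 18.5, 24.9, 25.0, 29.9, 30.0, 41.0]))
    assert list(cats) == [
        "underweight", "normal", "normal", "overweight", "overweight", "obese", "obese",
    ]


# --------------------------------------------------------------------------
# synthetic analysis frame helpers
# --------------------------------------------------------------------------


def _frame(n=4000, seed=0, true_or=2.0):
    """A well-behaved analysis frame with known exposure effect."""
    rng = np.random.default_rng(seed)
    exposure = (rng.random(n) < 0.3).astype(int)
    age = rng.uniform(20, 80, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    race = rng.choice(["european_ancestry", "african_ancestry", "other"], n, p=[0.7, 0.15, 0.15])
    bmi = rng.normal(27, 4, n)
    logit = -2.2 + math.log(true_or) * exposure + 0.03 * (age - 45) + 0.08 * (bmi - 27)
    outcome = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "outcome": outcome,
            "exposure": exposure,
            "age_years": age,
            "sex": sex,
            "race": race,
            "bmi_median": bmi,
            "hdl_median": rng.normal(51, 10, n),
            "tg_median": rng.normal(100, 30, n),
            "ehr_length_years": rng.uniform(0.5, 15, n),
            "median_ldl": np.where(exposure == 1, rng.uniform(25, 60, n), rng.uniform(90, 130, n)),
            "bmi_category": bmi_category(pd.Series(bmi)),
        }
    )


def test_adjusted_fit_recovers_known_or():
    result, _ = fit_logistic(_frame(n=20000, seed=3), ModelSpec(adjustment_set=ADJUSTMENT_FULL))
    assert result.converged
    assert result.ci_low <= 2.0 <= result.ci_high
    assert result.or_estimate == pytest.approx(2.0, rel=0.2)


def test_stratified_analysis_structure_and_accounting():
    frame = _frame(n=6000, seed=4)
    results = stratified_analysis(frame)
    strata = [r.stratum for r in results]
    assert strata == [
        "sex=female", "sex=male",
        "race=european_ancestry", "race=african_ancestry",
        "bmi=normal", "bmi=overweight", "bmi=obese",
        "ldl=ldl<40", "ldl=ldl40-60",
    ]
    # accounting identity: sex strata partition the complete cases
    total = results[0].n_cases + results[0].n_controls + results[1].n_cases + results[1].n_controls
    assert total == len(frame)
    # stratifying variable never adjusted within its own strata
    assert "sex" not in results[0].model.split("|")[1]


def test_sex_strata_cover_common_or():
    frame = _frame(n=20000, seed=5)
    results = stratified_analysis(frame)
    for r in results[:2]:
        assert r.converged
        assert r.ci_low <= 2.0 <= r.ci_high


def test_ldl_stratum_boundaries():
    frame = _frame(n=3000, seed=6)
    frame.loc[frame["exposure"] == 1, "median_ldl"] = 39.9
    below = stratified_analysis(frame)[7]
    frame.loc[frame["exposure"] == 1, "median_ldl"] = 40.0
    at = stratified_analysis(frame)[8]
    n_low = int((frame["exposure"] == 1).sum())
    assert below.n_cases + below.n_controls == len(frame)  # 39.9 → "<40"
    assert at.n_cases + at.n_controls == len(frame)  # 40.0 → "40–60"


def test_interaction_null_p_is_plausible_and_single_level_errors():
    frame = _frame(n=8000, seed=7)
    p, result = interaction_test(frame, "sex")
    assert result.converged
    assert 0.0 <= p <= 1.0
    frame_single = frame.assign(sex="female")
    with pytest.raises(ValueError):
        interaction_test(frame_single, "sex")
    with pytest.raises(ValueError):
        interaction_test(frame, "median_ldl")


def test_interaction_detects_strong_race_specific_effect():
    """Race-specific ORs (2.7 vs 1.1) must produce a small interaction p."""
    rng = np.random.default_rng(8)
    n = 50000
    exposure = (rng.random(n) < 0.3).astype(int)
    race = rng.choice(["european_ancestry", "african_ancestry"], n, p=[0.75, 0.25])
    log_or = np.where(race == "european_ancestry", math.log(2.7), math.log(1.1))
    logit = -2.3 + log_or * exposure
    frame = pd.DataFrame(
        {
            "outcome": (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int),
            "exposure": exposure,
            "age_years": rng.uniform(20, 80, n),
            "sex": rng.choice(["female", "male"], n),
            "race": race,
            "bmi_median": rng.normal(27, 4, n),
            "hdl_median": rng.normal(51, 10, n),
            "tg_median": rng.normal(100, 30, n),
            "ehr_length_years": rng.uniform(0.5, 15, n),
        }
    )
    p, _ = interaction_test(frame, "race")
    assert p < 0.01


# --------------------------------------------------------------------------
# sensitivity suite
# --------------------------------------------------------------------------


def _sensitivity_setup():
    """Six patients, each tripping exactly one sensitivity filter."""
    ids = [f"S{i}" for i in range(8)]
    frame = _frame(n=400, seed=9)
    frame.loc[: len(ids) - 1, "patient_id"] = ids
    frame["median_ldl_date"] = pd.Timestamp("2010-06-01")
    records = pd.DataFrame(
        {
            "patient_id": np.repeat(frame["patient_id"].to_numpy(), 2),
            "date": pd.Timestamp("2010-01-01"),
            "ldl_value": 55.0,
            "source": "friedewald",
            "triglycerides": 100.0,
            "excluded": False,
            "exclusion_reason": "none",
        }
    )
    # S0 has a single LDL record → dropped by filter (1)
    records = records.drop(records.index[records["patient_id"] == "S0"][1:])
    codes = make_codes(
        [
            ("S1", "2010-01-15", "250.00"),   # diabetes → 2a (within 30 d)
            ("S2", "2010-01-15", "410.90"),   # MI → 2a
            ("S3", "2010-01-15", "585.4"),    # CKD stage IV → 2b
            ("S4", "2010-01-15", "V42.0"),    # kidney transplant → 2b
            ("S5", "2010-01-15", "434.91"),   # stroke → 2c
            ("S6", "2010-03-15", "410.90"),   # MI 73 days after first LDL → retained
        ]
    )
    labs = make_labs([("S7", "2010-01-10", "egfr", 29.0)])  # → 2b
    meds = make_meds([("S2", "2012-01-01", "ezetimibe", "ezetimibe")])  # → 3
    patients = make_patients(
        [(pid, "1995-01-01" if pid == "S0" else "1960-01-01") for pid in frame["patient_id"]]
    )  # S0 is 15.4 y at the median date → filter (4)
    return frame, records, codes, labs, meds, patients


def _kept(results, frame):
    """patients retained per filter, inferred from complete-case counts."""
    return {r.stratum: r.n_cases + r.n_controls for r in results}


def test_sensitivity_filters_drop_exactly_the_flagged_patients():
    frame, records, codes, labs, meds, patients = _sensitivity_setup()
    results = sensitivity_suite(
        frame, records, codes, labs, meds, patients, PhecodeMap.bundled(), RunConfig()
    )
    n = len(frame)
    kept = _kept(results, frame)
    assert kept["sens1_min2_ldl"] == n - 1          # S0 only
    assert kept["sens2a_no_statin_indication"] == n - 2  # S1, S2
    assert kept["sens2b_also_no_renal_transplant"] == n - 5  # + S3, S4, S7
    assert kept["sens2c_also_no_stroke_pvd"] == n - 6       # + S5
    assert kept["sens3_no_ezetimibe"] == n - 1      # S2
    assert kept["sens4_adults_only"] == n - 1       # S0


def test_sensitivity_cohorts_nest():
    frame, records, codes, labs, meds, patients = _sensitivity_setup()
    results = sensitivity_suite(
        frame, records, codes, labs, meds, patients, PhecodeMap.bundled(), RunConfig()
    )
    kept = _kept(results, frame)
    assert (
        kept["sens2c_also_no_stroke_pvd"]
        <= kept["sens2b_also_no_renal_transplant"]
        <= kept["sens2a_no_statin_indication"]
    )


def test_egfr_boundary_29_vs_30():
    frame, records, codes, _, meds, patients = _sensitivity_setup()
    labs30 = make_labs([("S7", "2010-01-10", "egfr", 30.0)])
    results = sensitivity_suite(
        frame, records, codes, labs30, meds, patients, PhecodeMap.bundled(), RunConfig()
    )
    kept = _kept(results, frame)
    assert kept["sens2b_also_no_renal_transplant"] == len(frame) - 4  # S7 retained


def test_mi_code_35_days_after_first_ldl_retained():
    frame, records, _, labs, meds, patients = _sensitivity_setup()
    codes = make_codes([("S1", "2010-02-05", "410.90")])  # 35 days after 2010-01-01
    results = sensitivity_suite(
        frame, records, codes, labs, meds, patients, PhecodeMap.bundled(), RunConfig()
    )
    kept = _kept(results, frame)
    assert kept["sens2a_no_statin_indication"] == len(frame)


def test_stroke_code_substitution_toggle():
    frame, records, _, labs, meds, patients = _sensitivity_setup()
    codes = make_codes([("S5", "2010-01-15", "334.9")])
    default = sensitivity_suite(
        frame, records, codes, labs, meds, patients, PhecodeMap.bundled(), RunConfig()
    )
    swapped = sensitivity_suite(
        frame, records, codes, labs, meds, patients, PhecodeMap.bundled(),
        RunConfig(substitute_4339x_for_3349=True),
    )
    assert _kept(default, frame)["sens2c_also_no_stroke_pvd"] == len(frame) - 2
    assert _kept(swapped, frame)["sens2c_also_no_stroke_pvd"] == len(frame) - 1
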