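"""Odds-ratio estimation: 2×2 closed form and adjusted logistic models.

The Woolf estimator is implemented in closed form: OR = ad/bc with
log-scale standard error √(1/a + 1/b + 1/c + 1/d) and a normal-
approximation (Wald) interval and p-value. Adjusted models are binomial
logit fits by iteratively reweighted least squares (tolerance 1e-8, at
most 50 iterations) with Wald inference from the observed information;
for a single binary predictor the logistic odds ratio coincides exactly
with the cross-product ratio, which the test suite exploits as an
analytic identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "ModelSpec",
    "AssociationResult",
    "SeparationError",
    "odds_ratio_woolf",
    "expand_table",
    "fit_logistic",
    "wald_interaction_p",
    "ADJUSTMENT_NONE",
    "ADJUSTMENT_DEMOGRAPHIC",
    "ADJUSTMENT_FULL",
]

ADJUSTMENT_NONE: tuple[str, ...] = ()
ADJUSTMENT_DEMOGRAPHIC: tuple[str, ...] = ("age", "race", "sex", "bmi")
ADJUSTMENT_FULL: tuple[str, ...] = ("age", "race", "sex", "bmi", "ehr_length", "hdl", "tg")

#: analysis-frame column behind each adjustment term
_TERM_COLUMNS = {
    "age": "age_years",
    "bmi": "bmi_median",
    "ehr_length": "ehr_length_years",
    "hdl": "hdl_median",
    "tg": "tg_median",
}

MAX_ABS_COEF = 20.0  # |log-odds| beyond this is treated as separation


class SeparationError(RuntimeError):
    """Outcome perfectly separated (or degenerate); no finite MLE exists."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"ContingencyTable2x2.{name}: expected a count >= 0, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, exposure contrast, adjustment set, optional
    stratum restriction and interaction term."""

    outcome: str = "t2dm_algorithm"
    exposure: str = "low_ldl"
    adjustment_set: tuple[str, ...] = ADJUSTMENT_FULL
    stratum: tuple[str, str] | None = None  # (variable, level)
    interaction_term: str | None = None

    def __post_init__(self) -> None:
        known = {"age", "race", "sex", "bmi", "ehr_length", "hdl", "tg"}
        bad = set(self.adjustment_set) - known
        if bad:
            raise ValueError(f"ModelSpec: unknown adjustment terms {sorted(bad)}")
        if self.stratum is not None and self.stratum[0] in self.adjustment_set:
            raise ValueError(
                f"ModelSpec: stratifying variable {self.stratum[0]!r} must not appear in the adjustment set"
            )

    def describe(self) -> str:
        adj = "+".join(self.adjustment_set) if self.adjustment_set else "unadjusted"
        s = f"{self.outcome} ~ {self.exposure} | {adj}"
        if self.stratum:
            s += f" | stratum {self.stratum[0]}={self.stratum[1]}"
        if self.interaction_term:
            s += f" | interaction {self.exposure}x{self.interaction_term}"
        return s


@dataclass(frozen=True)
class AssociationResult:
    """One fitted comparison: OR with Wald 95% CI, p-value and counts."""

    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_controls: int
    model: str
    stratum: str = ""
    converged: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.converged and not (self.ci_low <= self.or_estimate <= self.ci_high):
            raise ValueError("AssociationResult: CI must bracket the estimate")

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "stratum": self.stratum,
            "or": self.or_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "converged": self.converged,
            "note": self.note,
        }


def odds_ratio_woolf(
    table: ContingencyTable2x2, alpha: float = 0.05, continuity_correction: bool = False
) -> AssociationResult:
    """Woolf odds ratio with normal-approximation CI and two-sided p-value."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            raise ValueError(
                "odds_ratio_woolf: zero cell; pass continuity_correction=True "
                "to add 0.5 to every cell (Haldane-Anscombe)"
            )
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return AssociationResult(
        or_estimate=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p),
        n_cases=table.a + table.c,
        n_controls=table.b + table.d,
        model="woolf_2x2",
    )


def expand_table(table: ContingencyTable2x2) -> pd.DataFrame:
    """Individual-level rows (outcome, exposure) reproducing the 2×2 counts."""
    outcome = np.concatenate(
        [np.ones(table.a), np.zeros(table.b), np.ones(table.c), np.zeros(table.d)]
    )
    exposure = np.concatenate(
        [np.ones(table.a + table.b), np.zeros(table.c + table.d)]
    )
    return pd.DataFrame({"outcome": outcome.astype(int), "exposure": exposure.astype(int)})


def _design_matrix(
    data: pd.DataFrame, adjustment_set: Sequence[str], interaction_term: str | None = None
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Build y, X (with intercept and dummy coding) and interaction columns.

    Race enters as two indicators against a European-ancestry reference
    (the 'other' category is retained as its own level); sex as a male
    indicator; BMI category — used only in interactions — as
    overweight/obese indicators against normal weight.
    """
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["exposure"] = data["exposure"].astype(float)
    for term in adjustment_set:
        if term == "race":
            X["race_african_ancestry"] = (data["race"] == "african_ancestry").astype(float)
            X["race_other"] = (data["race"] == "other").astype(float)
        elif term == "sex":
            X["sex_male"] = (data["sex"] == "male").astype(float)
        else:
            X[term] = data[_TERM_COLUMNS[term]].astype(float)
    inter_cols: list[str] = []
    if interaction_term:
        if interaction_term == "sex":
            bases = {"sex_male": (data["sex"] == "male").astype(float)}
        elif interaction_term == "race":
            bases = {
                "race_african_ancestry": (data["race"] == "african_ancestry").astype(float),
                "race_other": (data["race"] == "other").astype(float),
            }
        elif interaction_term == "bmi_category":
            bases = {
                "bmi_overweight": (data["bmi_category"] == "overweight").astype(float),
                "bmi_obese": (data["bmi_category"] == "obese").astype(float),
            }
        else:
            raise ValueError(f"interaction_term must be sex, race or bmi_category, got {interaction_term!r}")
        kept = {k: v for k, v in bases.items() if v.nunique() > 1}
        if not kept:
            raise ValueError(f"interaction variable {interaction_term!r} has a single level in these data")
        for name, base in kept.items():
            if name not in X.columns:
                X[name] = base
            col = f"exposure_x_{name}"
            X[col] = X["exposure"] * base
            inter_cols.append(col)
    y = data["outcome"].astype(float)
    return y, X, inter_cols


def fit_logistic(
    data: pd.DataFrame, model: ModelSpec, alpha: float = 0.05
) -> tuple[AssociationResult, object]:
    """Maximum-likelihood logistic fit; returns the result and the raw fit.

    ``data`` must carry ``outcome`` (0/1), ``exposure`` (0/1) and the
    analysis-frame covariate columns. Rows with missing values among the
    used columns are dropped (complete-case). A degenerate outcome raises
    :class:`SeparationError`; separation detected after fitting is
    reported as ``converged=False`` with a diagnostic note rather than a
    silent estimate.
    """
    y, X, inter_cols = _design_matrix(data, model.adjustment_set, model.interaction_term)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    n = len(y)
    if n == 0:
        raise ValueError("fit_logistic: no complete cases")
    if y.nunique() < 2:
        raise SeparationError("fit_logistic: outcome has a single class; model is degenerate")
    if X["exposure"].nunique() < 2:
        raise SeparationError("fit_logistic: exposure has a single level in the complete cases")
    n_params = X.shape[1]
    if n < 10 * n_params:
        import warnings

        warnings.warn(
            f"fit_logistic: only {n} complete cases for {n_params} parameters",
            stacklevel=2,
        )
    glm = sm.GLM(y, X, family=sm.families.Binomial())
    res = glm.fit(maxiter=50, tol=1e-8)

    params, bse = res.params, res.bse
    converged = bool(getattr(res, "converged", True))
    note = ""
    if (
        not np.all(np.isfinite(bse))
        or np.abs(params).max() > MAX_ABS_COEF
        or bse.max() > MAX_ABS_COEF
    ):
        converged = False
        note = "possible complete separation: unbounded coefficient or singular information"
    elif not converged:
        note = "IRLS did not converge within 50 iterations"

    z = sps.norm.ppf(1 - alpha / 2)
    beta, se = params["exposure"], bse["exposure"]
    n_cases = int(y.sum())
    if not converged:
        result = AssociationResult(
            or_estimate=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            n_cases=n_cases,
            n_controls=n - n_cases,
            model=model.describe(),
            stratum=f"{model.stratum[0]}={model.stratum[1]}" if model.stratum else "",
            converged=False,
            note=note,
        )
        return result, res
    result = AssociationResult(
        or_estimate=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p_value=float(2 * sps.norm.sf(abs(beta) / se)),
        n_cases=n_cases,
        n_controls=n - n_cases,
        model=model.describe(),
        stratum=f"{model.stratum[0]}={model.stratum[1]}" if model.stratum else "",
        converged=True,
        note=note,
    )
    return result, res


def wald_interaction_p(res) -> float:
    """Joint Wald p-value for every ``exposure_x_*`` product term in a fit."""
    names = list(res.model.exog_names)
    inter = [i for i, name in enumerate(names) if name.startswith("exposure_x_")]
    if not inter:
        raise ValueError("wald_interaction_p: the fit has no interaction terms")
    R = np.zeros((len(inter), len(names)))
    for row, idx in enumerate(inter):
        R[row, idx] = 1.0
    return float(res.wald_test(R, scalar=True).pvalue)
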