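"""Cohort splitting, logistic association analysis and the nomogram.

The clinical workflow mirrored here: a simple random 6:4 train/test split,
univariate logistic screens of each candidate predictor, a multivariate
logistic model of the collagen signature plus tumor location, tumor size
(>1 cm) and thyroid capsular invasion (TCI), and a points-based nomogram
re-parameterization of that model whose predicted probability is identical
to the logistic model's.

Odds ratios are Wald-based (exp of coefficient with normal-approximation
CI), matching conventional clinical reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

INTEGRATED_MODEL_VARIABLES = ("signature", "location_upper", "size_gt1cm", "tci")


@dataclass
class AssociationResult:
    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficient: float
    unstable: bool = False  # separation / non-identifiable fit

    def as_row(self) -> dict:
        return {"variable": self.variable, "OR": self.odds_ratio,
                "CI_low": self.ci_low, "CI_high": self.ci_high,
                "p": self.p_value, "coef": self.coefficient,
                "unstable": self.unstable}


def split_cohort(n_or_records, ratio: float = 0.6, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Simple random split; training size is round(ratio * n).

    Accepts either an integer n or a sequence of records/rows; returns
    (train_idx, test_idx) index arrays.  Deterministic under seed.
    """
    n = n_or_records if isinstance(n_or_records, (int, np.integer)) \
        else len(n_or_records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _wald_result(name: str, coef: float, se: float, p: float) -> AssociationResult:
    unstable = not np.isfinite(se) or se > 50 or abs(coef) > 50
    z = 1.959963984540054  # Phi^-1(0.975)

    def safe_exp(v: float) -> float:
        return float(np.exp(np.clip(v, -700, 700)))

    return AssociationResult(
        variable=name,
        odds_ratio=safe_exp(coef),
        ci_low=safe_exp(coef - z * se) if np.isfinite(se) else 0.0,
        ci_high=safe_exp(coef + z * se) if np.isfinite(se) else math.inf,
        p_value=float(p),
        coefficient=float(coef),
        unstable=bool(unstable),
    )


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = sm.add_constant(X, has_constant="add")
        try:
            return sm.Logit(y, design).fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # near-separation: IRLS with pseudo-inverse still yields Wald stats
            return sm.GLM(y, design, family=sm.families.Binomial()).fit()


def univariate_logistic(records: pd.DataFrame, variable: str,
                        outcome: str = "label") -> AssociationResult:
    """Single-predictor logistic fit with Wald OR, 95% CI and p-value."""
    y = records[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    x = records[[variable]].astype(float)
    if x[variable].nunique() < 2:
        raise ValueError(f"predictor {variable!r} is constant")
    res = _fit_logit(x, y)
    coef = res.params[variable]
    return _wald_result(variable, coef, res.bse[variable], res.pvalues[variable])


def multivariate_logistic(records: pd.DataFrame,
                          variables: tuple[str, ...] = INTEGRATED_MODEL_VARIABLES,
                          outcome: str = "label"
                          ) -> tuple[object, list[AssociationResult]]:
    """Joint logistic fit; returns the statsmodels result and per-variable
    adjusted Wald ORs.  Collinear duplicates and n <= #variables are errors;
    separation is flagged on the affected results, not raised."""
    y = records[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = records[list(variables)].astype(float)
    if len(records) <= len(variables):
        raise ValueError("need more records than predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()])) \
            < len(variables) + 1:
        raise ValueError("collinear predictors")
    res = _fit_logit(X, y)
    assoc = [_wald_result(v, res.params[v], res.bse[v], res.pvalues[v])
             for v in variables]
    return res, assoc


# ---------------------------------------------------------------------------
# nomogram
# ---------------------------------------------------------------------------

@dataclass
class NomogramModel:
    """Points re-parameterization of a logistic model.

    Each variable's contribution beta_v * x is mapped linearly to points so
    that the variable with the largest contribution span over the observed
    value ranges spans exactly 100 points; the total-points axis maps back
    to predicted probability through the inverse transformation, so the
    nomogram's probability is identical to the logistic model's.
    """

    variables: list[str]
    coefficients: dict[str, float]
    intercept: float
    value_ranges: dict[str, tuple[float, float]]
    points_per_unit: float = field(init=False)
    base_contribution: float = field(init=False)

    def __post_init__(self) -> None:
        spans = {v: abs(self.coefficients[v])
                 * (self.value_ranges[v][1] - self.value_ranges[v][0])
                 for v in self.variables}
        max_span = max(spans.values())
        # degenerate all-zero model: every record maps to sigmoid(intercept)
        self.points_per_unit = 100.0 / max_span if max_span > 0 else math.inf
        self.base_contribution = sum(
            min(self.coefficients[v] * self.value_ranges[v][0],
                self.coefficients[v] * self.value_ranges[v][1])
            for v in self.variables)

    def points(self, variable: str, value: float) -> float:
        lo, hi = self.value_ranges[variable]
        beta = self.coefficients[variable]
        if not (min(lo, hi) - 1e-9 <= value <= max(lo, hi) + 1e-9):
            raise ValueError(f"{variable}={value} outside the fitted range")
        if not math.isfinite(self.points_per_unit):
            return 0.0
        ref = min(beta * lo, beta * hi)
        return (beta * value - ref) * self.points_per_unit

    def total_points(self, record: dict | pd.Series) -> float:
        return sum(self.points(v, float(record[v])) for v in self.variables)

    def probability_from_points(self, total: float) -> float:
        scaled = total / self.points_per_unit \
            if math.isfinite(self.points_per_unit) else 0.0
        return float(expit(self.intercept + self.base_contribution + scaled))

    def predict(self, record: dict | pd.Series) -> float:
        return self.probability_from_points(self.total_points(record))

    def max_points_variable(self) -> str:
        spans = {v: abs(self.coefficients[v])
                 * (self.value_ranges[v][1] - self.value_ranges[v][0])
                 for v in self.variables}
        return max(spans, key=spans.get)


def build_nomogram(result, records: pd.DataFrame,
                   variables: tuple[str, ...] = INTEGRATED_MODEL_VARIABLES) -> NomogramModel:
    """Standard points construction from a fitted multivariate logit."""
    coefs = {v: float(result.params[v]) for v in variables}
    ranges = {v: (float(records[v].min()), float(records[v].max()))
              for v in variables}
    return NomogramModel(list(variables), coefs, float(result.params["const"]),
                         ranges)


def nomogram_predict(nomo: NomogramModel, record: dict | pd.Series) -> float:
    return nomo.predict(record)


class NomogramClassifier(ClassifierMixin, BaseEstimator):
    """Multivariate logistic CLNM model with its nomogram, sklearn-style.

    ``fit`` expects a DataFrame whose columns include the model variables
    (by default the signature + the three clinical covariates).  Fitted
    attributes: ``result_`` (statsmodels), ``associations_`` (adjusted Wald
    ORs), ``nomogram_``.
    """

    def __init__(self, variables: tuple[str, ...] = INTEGRATED_MODEL_VARIABLES):
        self.variables = variables

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        df = X.copy()
        df["label"] = y
        self.result_, self.associations_ = multivariate_logistic(
            df, tuple(self.variables))
        self.nomogram_ = build_nomogram(self.result_, df, tuple(self.variables))
        self.coef_ = np.array([self.result_.params[v] for v in self.variables])
        self.intercept_ = float(self.result_.params["const"])
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "result_")
        M = X[list(self.variables)].to_numpy(dtype=float)
        return self.intercept_ + M @ self.coef_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)

    def association_table(self) -> pd.DataFrame:
        check_is_fitted(self, "result_")
        return pd.DataFrame([a.as_row() for a in self.associations_])
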