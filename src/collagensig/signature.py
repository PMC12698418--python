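"""Collagen-signature construction: train-only z-scoring and LASSO selection.

The signature is the linear predictor of an L1-penalized logistic regression
fit on the training cohort only: features are standardized with training
means/SDs (applied unchanged to any later cohort — never refit), the penalty
weight lambda is chosen by 5-fold stratified cross-validation minimizing
mean binomial deviance on a 100-point log-spaced grid descending from
lambda_max (the smallest penalty that zeroes every coefficient), and the
signature of a patient is  intercept + sum_i coef_i * z_i  over the selected
features.

`CollagenSignature` is the scikit-learn estimator form; the module-level
functions (`fit_normalizer`, `fit_lasso_signature`, `compute_signature`)
expose the same steps functionally and power the estimator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted


@dataclass
class Normalizer:
    """Per-feature z-score parameters estimated on the training cohort."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray                      # sample SD (ddof=1)
    dropped: list[str] = field(default_factory=list)  # zero-variance features

    def transform(self, X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if names is not None and names != self.feature_names:
            idx = [names.index(n) for n in self.feature_names]
            X = X[:, idx]
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature count mismatch with normalizer")
        return (X - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"feature_names": self.feature_names, "mean": self.mean.tolist(),
                "sd": self.sd.tolist(), "dropped": self.dropped}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(d["feature_names"], np.array(d["mean"]), np.array(d["sd"]),
                   list(d.get("dropped", [])))


@dataclass
class SignatureModel:
    """Frozen LASSO-logistic signature: selected features and coefficients."""

    feature_names: list[str]            # features entering the model (post-drop)
    selected_features: list[str]        # nonzero-coefficient subset
    coefficients: np.ndarray            # aligned with selected_features
    intercept: float
    lambda_: float
    log_lambda: float
    n_folds: int
    seed: int
    fold_assignments: np.ndarray | None = None
    cv_deviance: np.ndarray | None = None
    lambda_grid: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "selected_features": self.selected_features,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "log_lambda": self.log_lambda,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "fold_assignments": None if self.fold_assignments is None
            else self.fold_assignments.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(d["feature_names"], d["selected_features"],
                   np.array(d["coefficients"]), d["intercept"], d["lambda"],
                   d["log_lambda"], d["n_folds"], d["seed"],
                   None if d.get("fold_assignments") is None
                   else np.array(d["fold_assignments"]))


def fit_normalizer(train_features: np.ndarray,
                   feature_names: list[str] | None = None) -> Normalizer:
    """Estimate z-score parameters from training rows only (sample SD).

    Zero-variance features are dropped with a warning and listed on the
    returned object; the same parameters must be applied, never refit, to
    any test cohort.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 training patients")
    names = list(feature_names) if feature_names is not None \
        else [f"f{i}" for i in range(X.shape[1])]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s)",
                      stacklevel=2)
    kept_names = [n for n, k in zip(names, keep) if k]
    return Normalizer(kept_names, mean[keep], sd[keep], dropped)


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int,
                 min_ratio: float) -> np.ndarray:
    n = len(y)
    ybar = y.mean()
    lam_max = np.abs(X.T @ (y - ybar)).max() / n
    lam_max = max(lam_max, 1e-12)
    return np.exp(np.linspace(np.log(lam_max), np.log(lam_max * min_ratio),
                              n_lambdas))


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # glmnet objective (1/n)*nll + lam*||w||_1  <=>  sklearn C = 1/(n*lam);
    # saga leaves the intercept unpenalized, matching glmnet
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="saga", tol=1e-7,
                             max_iter=5000, random_state=0)
    clf.fit(X, y)
    return clf


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_lasso_signature(X: np.ndarray, y: np.ndarray, folds: int = 5,
                        seed: int = 0, n_lambdas: int = 100,
                        lambda_min_ratio: float = 1e-4,
                        feature_names: list[str] | None = None) -> SignatureModel:
    """LASSO logistic regression with stratified K-fold CV choice of lambda.

    ``X`` must already be standardized (training z-scores).  The grid runs
    from lambda_max down by a factor of ``lambda_min_ratio``; lambda* is the
    CV-deviance minimizer and the final model is refit at lambda* on all
    training rows.  Deterministic given (data, seed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("y must contain both outcome classes")
    if not set(classes).issubset({0.0, 1.0}):
        raise ValueError("y must be binary 0/1")
    if len(y) < folds:
        raise ValueError("fewer patients than CV folds")
    names = list(feature_names) if feature_names is not None \
        else [f"f{i}" for i in range(X.shape[1])]

    grid = _lambda_grid(X, y, n_lambdas, lambda_min_ratio)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(y), dtype=int)
    splits = list(skf.split(X, y))
    for k, (_, va) in enumerate(splits):
        fold_of[va] = k

    # warm-started coordinate/saga path per fold, descending lambda (the
    # standard pathwise strategy): each solution seeds the next, so the few
    # iterations per grid point suffice for an accurate CV deviance curve
    dev = np.zeros((folds, len(grid)))
    with warnings.catch_warnings():
        # capped iterations per grid point are intentional on the warm path
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for k, (tr, va) in enumerate(splits):
            clf = LogisticRegression(l1_ratio=1.0, solver="saga",
                                     warm_start=True, max_iter=50, tol=1e-4,
                                     random_state=0)
            for j, lam in enumerate(grid):
                clf.C = 1.0 / (len(tr) * lam)
                clf.fit(X[tr], y[tr])
                p = clf.predict_proba(X[va])[:, 1]
                dev[k, j] = _binomial_deviance(y[va], p)
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    lam_star = float(grid[best])

    final = _l1_logistic(X, y, lam_star)
    coefs = final.coef_.ravel()
    nz = np.flatnonzero(np.abs(coefs) > 1e-10)
    return SignatureModel(
        feature_names=names,
        selected_features=[names[i] for i in nz],
        coefficients=coefs[nz],
        intercept=float(final.intercept_[0]),
        lambda_=lam_star,
        log_lambda=float(np.log(lam_star)),
        n_folds=folds,
        seed=seed,
        fold_assignments=fold_of,
        cv_deviance=mean_dev,
        lambda_grid=grid,
    )


def compute_signature(model: SignatureModel, features: np.ndarray,
                      normalizer: Normalizer,
                      feature_names: list[str] | None = None) -> np.ndarray:
    """Scalar signature(s): intercept + sum coef_i * z_i over selected features."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    Z = normalizer.transform(X, feature_names)
    idx = []
    for name in model.selected_features:
        if name not in model.feature_names:
            raise KeyError(f"selected feature {name!r} missing from model schema")
        idx.append(normalizer.feature_names.index(name))
    contrib = Z[:, idx] @ model.coefficients if idx else np.zeros(len(Z))
    return model.intercept + contrib


class CollagenSignature(TransformerMixin, BaseEstimator):
    """Scikit-learn estimator form of the collagen-signature pipeline.

    ``fit(X, y)`` learns the training z-score parameters and the CV-LASSO
    model; ``decision_function(X)`` (= ``transform``) returns the scalar
    signature per patient using the frozen training parameters.

    Parameters
    ----------
    folds : CV fold count for the lambda search (5 in the emulated design).
    seed : controls fold shuffling; identical (data, seed) give identical
        selected features and coefficients.
    n_lambdas, lambda_min_ratio : geometry of the penalty grid.
    """

    def __init__(self, folds: int = 5, seed: int = 0, n_lambdas: int = 100,
                 lambda_min_ratio: float = 1e-4):
        self.folds = folds
        self.seed = seed
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio

    def fit(self, X, y, feature_names: list[str] | None = None):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
        self.feature_names_in_ = list(feature_names)
        self.normalizer_ = fit_normalizer(X, feature_names)
        Z = self.normalizer_.transform(X, feature_names)
        self.model_ = fit_lasso_signature(
            Z, y, folds=self.folds, seed=self.seed, n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            feature_names=self.normalizer_.feature_names)
        self.selected_features_ = self.model_.selected_features
        self.coef_ = self.model_.coefficients
        self.intercept_ = self.model_.intercept
        self.lambda_ = self.model_.lambda_
        self.log_lambda_ = self.model_.log_lambda
        return self

    def decision_function(self, X) -> np.ndarray:
        import pandas as pd

        check_is_fitted(self, "model_")
        names = None
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        names = names or self.feature_names_in_
        return compute_signature(self.model_, X, self.normalizer_, names)

    def transform(self, X) -> np.ndarray:
        return self.decision_function(X).reshape(-1, 1)

    def save(self, path: str | Path) -> None:
        payload = {"normalizer": self.normalizer_.to_dict(),
                   "model": self.model_.to_dict(),
                   "feature_names_in": self.feature_names_in_}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CollagenSignature":
        payload = json.loads(Path(path).read_text())
        est = cls()
        est.normalizer_ = Normalizer.from_dict(payload["normalizer"])
        est.model_ = SignatureModel.from_dict(payload["model"])
        est.feature_names_in_ = payload["feature_names_in"]
        est.selected_features_ = est.model_.selected_features
        est.coef_ = est.model_.coefficients
        est.intercept_ = est.model_.intercept
        est.lambda_ = est.model_.lambda_
        est.log_lambda_ = est.model_.log_lambda
        return est
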