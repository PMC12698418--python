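"""Discrimination, calibration and clinical-utility metrics.

Everything operates on (scores-or-probabilities, binary labels) pairs so any
probability-producing model can be evaluated: Mann-Whitney AUC (C-index is
its named alias for binary outcomes), percentile bootstrap CIs with
stratified resampling, DeLong's test for paired AUCs, confusion-matrix
metrics at a Youden-or-fixed threshold, quantile-binned calibration curves,
and decision-curve analysis with the treat-all / treat-none references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_curve


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney concordance probability with half credit for ties.

    Computed from midranks: AUC = (R_pos - m(m+1)/2) / (m n), where R_pos is
    the midrank sum of the positive scores.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    ranks = sstats.rankdata(s)
    m = int(y.sum())
    n = len(y) - m
    return float((ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n))


def c_index(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Concordance index; for a binary outcome this equals the ROC AUC."""
    return roc_auc(scores, labels)


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Score threshold maximizing Youden's J = sensitivity + specificity - 1."""
    y = _check_binary(labels)
    fpr, tpr, thresh = roc_curve(y, np.asarray(scores, dtype=float))
    j = tpr - fpr
    return float(thresh[int(np.argmax(j))])


def bootstrap_ci(metric_fn: Callable[[np.ndarray, np.ndarray], float],
                 scores: Sequence[float], labels: Sequence[int],
                 B: int = 1000, seed: int = 0, stratified: bool = True,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI of metric_fn(scores, labels).

    Resamples are stratified by label by default; a resample that loses a
    class is redrawn (attempts capped at 10*B).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    rng = np.random.default_rng(seed)
    n = len(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    vals = np.empty(B)
    attempts = 0
    b = 0
    while b < B:
        if stratified:
            idx = np.concatenate([rng.choice(pos, len(pos)),
                                  rng.choice(neg, len(neg))])
        else:
            idx = rng.integers(0, n, n)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            attempts += 1
            if attempts > 10 * B:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        vals[b] = metric_fn(scores[idx], yb)
        b += 1
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# DeLong's test for paired AUCs
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Mid-rank placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    ranks_all = sstats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = sstats.rankdata(pos)
    ranks_neg = sstats.rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n          # P(neg < pos) with tie credit
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> tuple[float, float]:
    """Two-sided DeLong test for a difference between paired AUCs.

    Returns (AUC_a - AUC_b, p).  If the variance of the difference is zero
    and the difference itself is zero (e.g. identical scores), p = 1.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    v10_a, v01_a, auc_a = _placements(a, y)
    v10_b, v01_b, auc_b = _placements(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = 2.0 * sstats.norm.sf(abs(z))
    return float(delta), float(p)


# ---------------------------------------------------------------------------
# decision curves, classification metrics, calibration
# ---------------------------------------------------------------------------

def decision_curve(probs: Sequence[float], labels: Sequence[int],
                   thresholds: Sequence[float] | None = None) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none strategies.

    net_benefit(t) = TP(t)/n - FP(t)/n * t/(1-t), classifying positive when
    prob >= t; treat-none is identically zero and treat-all is
    prevalence - (1 - prevalence) * t/(1-t).
    """
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = _check_binary(labels)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    t = np.asarray(thresholds, dtype=float)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for ti in t:
        pred = p >= ti
        tp = float(np.sum(pred & (y == 1)))
        fp = float(np.sum(pred & (y == 0)))
        w = ti / (1 - ti)
        rows.append({
            "threshold": ti,
            "net_benefit_model": tp / n - fp / n * w,
            "net_benefit_all": prev - (1 - prev) * w,
            "net_benefit_none": 0.0,
        })
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Tabular performance summary of a probability model on one cohort."""

    auc: float
    auc_ci: tuple[float, float]
    c_index: float
    threshold: float
    metrics: dict[str, float]                       # sensitivity, ..., accuracy
    metric_cis: dict[str, tuple[float, float]]
    confusion: dict[str, int]                       # TP, FN, FP, TN
    calibration: pd.DataFrame | None = None
    decision: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for name, val in self.metrics.items():
            lo, hi = self.metric_cis.get(name, (np.nan, np.nan))
            rows.append({"metric": name, "value": val, "CI_low": lo, "CI_high": hi})
        return pd.DataFrame(rows)


def confusion_counts(probs: np.ndarray, labels: np.ndarray,
                     threshold: float) -> dict[str, int]:
    pred = np.asarray(probs, dtype=float) >= threshold
    y = np.asarray(labels) == 1
    return {"TP": int(np.sum(pred & y)), "FN": int(np.sum(~pred & y)),
            "FP": int(np.sum(pred & ~y)), "TN": int(np.sum(~pred & ~y))}


def _confusion_metrics(probs: np.ndarray, labels: np.ndarray,
                       threshold: float) -> dict[str, float]:
    c = confusion_counts(probs, labels, threshold)
    tp, fn, fp, tn = c["TP"], c["FN"], c["FP"], c["TN"]

    def ratio(a: float, b: float) -> float:
        return a / b if b > 0 else 0.0

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
    }


def classification_metrics(probs: Sequence[float], labels: Sequence[int],
                           threshold: float, B: int = 1000, seed: int = 0
                           ) -> tuple[dict[str, float],
                                      dict[str, tuple[float, float]],
                                      dict[str, int]]:
    """Sensitivity/specificity/PPV/NPV/accuracy at a threshold, with
    percentile-bootstrap 95% CIs from the shared bootstrap engine."""
    if not 0.0 < threshold < 1.0 and not np.isfinite(threshold):
        raise ValueError("threshold must be a finite probability")
    p = np.asarray(probs, dtype=float)
    y = _check_binary(labels)
    point = _confusion_metrics(p, y, threshold)
    cis = {}
    for name in point:
        fn = (lambda s, l, _n=name: _confusion_metrics(s, l, threshold)[_n])
        cis[name] = bootstrap_ci(fn, p, y, B=B, seed=seed)
    return point, cis, confusion_counts(p, y, threshold)


def calibration_curve(probs: Sequence[float], labels: Sequence[int],
                      bins: int = 10) -> pd.DataFrame:
    """Mean predicted vs observed outcome frequency per predicted-risk
    quantile bin; empty bins are merged with their neighbor."""
    if bins < 3:
        raise ValueError("need at least 3 bins")
    p = np.asarray(probs, dtype=float)
    y = _check_binary(labels)
    edges = np.unique(np.quantile(p, np.linspace(0, 1, bins + 1)))
    if len(edges) < 3:  # nearly-constant predictions: single usable bin
        edges = np.array([p.min() - 1e-9, p.max() + 1e-9])
    which = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        rows.append({"bin": b, "n": int(sel.sum()),
                     "mean_predicted": float(p[sel].mean()),
                     "observed": float(y[sel].mean())})
    return pd.DataFrame(rows)


def evaluate_model(probs: Sequence[float], labels: Sequence[int],
                   threshold: float, B: int = 1000, seed: int = 0,
                   thresholds_dca: Sequence[float] | None = None
                   ) -> EvaluationReport:
    """Full cohort report: AUC with bootstrap CI, classification metrics at the
    given threshold, calibration curve and decision curve."""
    p = np.asarray(probs, dtype=float)
    y = _check_binary(labels)
    auc = roc_auc(p, y)
    auc_ci = bootstrap_ci(roc_auc, p, y, B=B, seed=seed)
    metrics, cis, conf = classification_metrics(p, y, threshold, B=B, seed=seed)
    return EvaluationReport(
        auc=auc, auc_ci=auc_ci, c_index=auc, threshold=threshold,
        metrics=metrics, metric_cis=cis, confusion=conf,
        calibration=calibration_curve(p, y),
        decision=decision_curve(p, y, thresholds_dca),
    )
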