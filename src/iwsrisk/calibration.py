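"""Probability calibration and the evaluation surface.

Platt scaling refits a one-dimensional logistic regression on the
validation split, mapping raw model scores to calibrated probabilities:
p_cal = sigmoid(A * logit(p_raw) + B).  Because the map is strictly
monotone for A > 0, rank-based metrics (AUROC, AUPRC) are unchanged;
only threshold values and calibration error move.

Evaluation mirrors the usual clinical reporting style: operating points
at fixed sensitivity targets with the full confusion-table metric row,
ROC and precision-recall curves with their areas, and a reliability
curve with expected calibration error (ECE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit as _logit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

_CLIP = 1e-7


@dataclass
class PlattCalibrator:
    """Logistic recalibration of raw scores: sigmoid(A * logit(p) + B)."""

    A: float = 1.0
    B: float = 0.0
    fitted: bool = False

    def __call__(self, p_raw: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("calibrator not fitted")
        z = _logit(np.clip(p_raw, _CLIP, 1 - _CLIP))
        return expit(self.A * z + self.B)


def fit_platt(p_raw: np.ndarray, labels: np.ndarray) -> PlattCalibrator:
    """Fit the calibration map on validation scores and labels.

    The logistic regression is effectively unregularised (C = 1e6) so the
    fitted slope/intercept are maximum-likelihood.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("validation labels are single-class; cannot calibrate")
    z = _logit(np.clip(np.asarray(p_raw, dtype=float), _CLIP, 1 - _CLIP))
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(z.reshape(-1, 1), labels)
    return PlattCalibrator(A=float(lr.coef_[0, 0]), B=float(lr.intercept_[0]), fitted=True)


def apply_platt(calibrator: PlattCalibrator, p_raw: np.ndarray) -> np.ndarray:
    return calibrator(np.asarray(p_raw, dtype=float))


@dataclass
class MetricRow:
    """Confusion-table metrics at one fixed-sensitivity operating point."""

    target_sensitivity: float
    threshold: float
    achieved_sensitivity: float
    precision: float
    accuracy: float
    specificity: float
    npv: float
    f1: float
    tp: int
    fn: int
    fp: int
    tn: int


def confusion_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    """All rates from the confusion table with positives at score >= threshold."""
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(scores) >= threshold
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return dict(
        tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity=sens, precision=prec, specificity=spec, npv=npv,
        accuracy=acc, f1=f1,
    )


def metrics_at_sensitivity(
    scores: np.ndarray, labels: np.ndarray, target_sensitivity: float
) -> MetricRow:
    """Operating point at the largest threshold reaching the target sensitivity.

    Samples scoring at or above the threshold are called positive, so the
    achieved sensitivity is always >= the target (threshold below the
    minimum positive score gives sensitivity 1).
    """
    if not 0.0 < target_sensitivity <= 1.0:
        raise ValueError("target_sensitivity must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    pos_scores = np.sort(scores[labels == 1])[::-1]
    n_pos = len(pos_scores)
    # smallest number of captured positives satisfying the target
    k = int(np.ceil(target_sensitivity * n_pos))
    threshold = pos_scores[k - 1]
    m = confusion_metrics(scores, labels, threshold)
    return MetricRow(
        target_sensitivity=target_sensitivity,
        threshold=float(threshold),
        achieved_sensitivity=m["sensitivity"],
        precision=m["precision"],
        accuracy=m["accuracy"],
        specificity=m["specificity"],
        npv=m["npv"],
        f1=m["f1"],
        tp=m["tp"],
        fn=m["fn"],
        fp=m["fp"],
        tn=m["tn"],
    )


DEFAULT_SENSITIVITY_GRID = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95)


def sensitivity_table(
    scores: np.ndarray,
    labels: np.ndarray,
    targets: tuple[float, ...] = DEFAULT_SENSITIVITY_GRID,
) -> pd.DataFrame:
    rows = [metrics_at_sensitivity(scores, labels, t) for t in targets]
    return pd.DataFrame([r.__dict__ for r in rows])


def roc_pr(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC and PR curves with their areas.

    AUROC is the trapezoidal area over all distinct thresholds (equal-score
    ties grouped); AUPRC is the step-wise average-precision sum.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thr,
        "auroc": float(roc_auc_score(labels, scores)),
        "precision": prec,
        "recall": rec,
        "pr_thresholds": pr_thr,
        "auprc": float(average_precision_score(labels, scores)),
    }


def calibration_curve(
    probabilities: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> tuple[pd.DataFrame, float]:
    """Reliability curve on equal-width bins plus expected calibration error.

    ECE = sum_b (count_b / N) * |mean_pred_b - observed_freq_b| over
    non-empty bins.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    ece = 0.0
    n = len(p)
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        if count == 0:
            continue
        mean_pred = float(p[mask].mean())
        obs = float(y[mask].mean())
        ece += count / n * abs(mean_pred - obs)
        rows.append(
            {"bin": b, "mean_predicted": mean_pred, "observed_frequency": obs, "count": count}
        )
    return pd.DataFrame(rows), float(ece)
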