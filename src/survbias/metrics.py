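"""Evaluation statistics for binary classifiers of survey outcomes.

Implements the full metric suite used by the robustness protocol: accuracy,
recall, positive/negative precision, binary and support-weighted F1, Cohen's
kappa, error rate, binary cross-entropy loss, ROC AUC, vertical ROC averaging
across folds, and the composite model-selection score

    CS = w1 * AUC + w2 * kappa * H(recall),

where H is the Heaviside step (H(x) = 1 for x > 0, else 0): the chance-corrected
agreement term only counts when the model recovers at least one true positive.
Default weights are w1 = 2, w2 = 0.25, prioritising discrimination.

Degenerate ratios (zero denominators) return 0 with a logged warning — the
convention under which a classifier that never predicts the positive class
reports positive precision 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CompositeWeights",
    "confusion",
    "basic_rates",
    "f1_weighted",
    "cohens_kappa",
    "cross_entropy",
    "auc",
    "composite_score",
    "heaviside",
    "average_roc",
    "compute_report",
]

logger = logging.getLogger(__name__)

SCORE_EPS = 1e-15  # clipping floor for probabilities entering the log-loss
FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class CompositeWeights:
    w1: float = 2.0
    w2: float = 0.25

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 <= 0:
            raise ValueError("composite weights must be non-negative with positive sum")


@dataclass
class MetricsReport:
    """All per-evaluation metrics; computing_time_s is reported, never asserted."""

    accuracy: float
    recall: float
    positive_precision: float
    negative_precision: float
    f1_binary: float
    f1_weighted: float
    cohens_kappa: float
    error_rate: float
    loss: float
    auc: float
    composite: float
    computing_time_s: float = 0.0

    FIELDS = ("accuracy", "recall", "f1_weighted", "cohens_kappa", "positive_precision",
              "negative_precision", "error_rate", "loss", "auc", "composite",
              "f1_binary", "computing_time_s")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


def _check_binary(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise ValueError("inputs must be equal-length 1-D vectors with length >= 1")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    return y_true.astype(int), y_pred.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true, y_pred = _check_binary(y_true, y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _ratio(num: float, den: float, label: str) -> float:
    if den == 0:
        logger.warning("undefined %s (zero denominator); returning 0 by convention", label)
        return 0.0
    return num / den


def basic_rates(c: ConfusionCounts):
    """(accuracy, recall, positive_precision, negative_precision, f1_binary, error_rate)."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (c.TP + c.TN) / c.total
    recall = _ratio(c.TP, c.TP + c.FN, "recall")
    pos_prec = _ratio(c.TP, c.TP + c.FP, "positive precision")
    neg_prec = _ratio(c.TN, c.TN + c.FN, "negative precision")
    f1 = _ratio(2 * pos_prec * recall, pos_prec + recall, "F1")
    return accuracy, recall, pos_prec, neg_prec, f1, 1.0 - accuracy


def f1_weighted(y_true, y_pred) -> float:
    """Support-weighted mean of the two per-class F1 scores."""
    y_true, y_pred = _check_binary(y_true, y_pred)
    n = len(y_true)
    total = 0.0
    for cls in (0, 1):
        support = int(np.sum(y_true == cls))
        if support == 0:
            continue
        c = confusion((y_true == cls).astype(int), (y_pred == cls).astype(int))
        _, rec, prec, _, f1, _ = basic_rates(c)
        total += support / n * f1
    return total


def cohens_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e); 0 when p_e = 1."""
    c = confusion(y_true, y_pred)
    n = c.total
    p_o = (c.TP + c.TN) / n
    p_e = ((c.TP + c.FP) * (c.TP + c.FN) + (c.TN + c.FP) * (c.TN + c.FN)) / n**2
    if abs(1.0 - p_e) < 1e-15:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def cross_entropy(y_true, p_scores) -> float:
    """Mean binary cross-entropy with scores clipped to [eps, 1-eps], eps = 1e-15."""
    y_true = np.asarray(y_true, dtype=float)
    p = np.asarray(p_scores, dtype=float)
    if y_true.shape != p.shape:
        raise ValueError("length mismatch")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("scores must lie in [0,1]")
    p = np.clip(p, SCORE_EPS, 1.0 - SCORE_EPS)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


def auc(y_true, p_scores) -> float:
    """ROC AUC via the normalized Mann-Whitney U statistic (ties counted 1/2)."""
    y_true = np.asarray(y_true).astype(int)
    p = np.asarray(p_scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: only one class present")
    ranks = rankdata(p)  # average ranks handle ties as 1/2
    u = float(np.sum(ranks[y_true == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def heaviside(x: float) -> float:
    """Step function: 1 for x > 0, 0 for x <= 0 (zero and negatives gate off)."""
    return 1.0 if x > 0 else 0.0


def composite_score(auc_value: float, kappa: float, recall: float,
                    weights: CompositeWeights = CompositeWeights(),
                    gate: str = "recall") -> float:
    """CS = w1*AUC + w2*kappa*H(recall) (default), or w2*recall*H(kappa) with gate='kappa'.

    The recall-gated parse is the default; the alternative parse of the gated
    product is available for comparison.
    """
    if gate == "recall":
        return weights.w1 * auc_value + weights.w2 * kappa * heaviside(recall)
    if gate == "kappa":
        return weights.w1 * auc_value + weights.w2 * recall * heaviside(kappa)
    raise ValueError(f"unknown gate {gate!r}")


def roc_points(y_true, p_scores):
    """Empirical ROC as (fpr, tpr) arrays, thresholds descending, endpoints included."""
    y_true = np.asarray(y_true).astype(int)
    p = np.asarray(p_scores, dtype=float)
    order = np.argsort(-p, kind="stable")
    y = y_true[order]
    ps = p[order]
    distinct = np.r_[np.flatnonzero(np.diff(ps)), len(ps) - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    n_pos = max(int(y.sum()), 1)
    n_neg = max(len(y) - int(y.sum()), 1)
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return fpr, tpr


def average_roc(per_fold_curves, per_fold_aucs=None):
    """Vertical ROC averaging on a fixed 101-point FPR grid.

    per_fold_curves: iterable of (fpr, tpr) arrays. Returns (fpr_grid, mean_tpr,
    mean_auc) where mean_auc is the mean of the per-fold AUCs (computed by
    trapezoid on each fold curve when not supplied) — not the AUC of the mean curve.
    """
    curves = list(per_fold_curves)
    if not curves:
        raise ValueError("need at least one fold curve")
    tprs = []
    aucs = []
    for fpr, tpr in curves:
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
        aucs.append(float(np.trapezoid(tpr, fpr)))
    mean_tpr = np.mean(tprs, axis=0)
    mean_auc = float(np.mean(per_fold_aucs)) if per_fold_aucs is not None else float(np.mean(aucs))
    return FPR_GRID.copy(), mean_tpr, mean_auc


def compute_report(y_true, p_scores, weights: CompositeWeights = CompositeWeights(),
                   threshold: float = 0.5, computing_time_s: float = 0.0) -> MetricsReport:
    """Full metric report at the given probability threshold (default 0.5)."""
    y_true = np.asarray(y_true).astype(int)
    p = np.asarray(p_scores, dtype=float)
    y_pred = (p > threshold).astype(int)
    c = confusion(y_true, y_pred)
    accuracy, recall, pos_prec, neg_prec, f1b, err = basic_rates(c)
    kappa = cohens_kappa(y_true, y_pred)
    try:
        auc_value = auc(y_true, p)
    except UndefinedMetricError:
        logger.warning("single-class evaluation set; AUC reported as 0.5")
        auc_value = 0.5
    return MetricsReport(
        accuracy=accuracy,
        recall=recall,
        positive_precision=pos_prec,
        negative_precision=neg_prec,
        f1_binary=f1b,
        f1_weighted=f1_weighted(y_true, y_pred),
        cohens_kappa=kappa,
        error_rate=err,
        loss=cross_entropy(y_true, p),
        auc=auc_value,
        composite=composite_score(auc_value, kappa, recall, weights),
        computing_time_s=computing_time_s,
    )
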