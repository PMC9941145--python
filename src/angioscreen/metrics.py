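"""Statistical metric kernels shared by all stage reports.

All classification kernels operate on a confusion matrix (rows = truth,
columns = prediction); AUC operates on scores. Edge cases that matter for
small validation folds are handled explicitly: chance agreement of 1 yields a
kappa of 0 (flagged), single-class truth sets yield ``None`` for AUC instead
of a number, and zero-support classes are excluded from the weighted F1.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["confusion_matrix", "accuracy", "cohen_kappa", "weighted_f1",
           "roc_auc", "macro_ovr_auc", "sensitivity", "specificity"]


def confusion_matrix(truths, predictions, n_classes: int) -> np.ndarray:
    """Integer count matrix with rows = truth categories, columns = predicted."""
    truths = np.asarray(truths, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if truths.shape != predictions.shape:
        raise ValueError("truths and predictions must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (truths, predictions), 1)
    return cm


def _validate_cm(cm) -> np.ndarray:
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if cm.sum() <= 0 or (cm < 0).any():
        raise ValueError("confusion matrix must be non-negative with total > 0")
    return cm


def accuracy(cm) -> float:
    cm = _validate_cm(cm)
    return float(np.trace(cm) / cm.sum())


def cohen_kappa(cm, return_flag: bool = False):
    """(p_o - p_e) / (1 - p_e); defined as 0 (flagged) when p_e = 1."""
    cm = _validate_cm(cm)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    if np.isclose(p_e, 1.0):
        return (0.0, True) if return_flag else 0.0
    kappa = float((p_o - p_e) / (1.0 - p_e))
    return (kappa, False) if return_flag else kappa


def weighted_f1(cm) -> float:
    """Support-weighted mean of per-class F1; zero-support classes excluded."""
    cm = _validate_cm(cm)
    support = cm.sum(axis=1)
    f1s, weights = [], []
    for c in range(cm.shape[0]):
        if support[c] == 0:
            continue
        tp = cm[c, c]
        denom = 2 * tp + (cm[:, c].sum() - tp) + (support[c] - tp)
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
        weights.append(support[c])
    return float(np.average(f1s, weights=weights))


def sensitivity(cm, positive: int | None = None) -> float:
    """Recall of class `positive`; macro-averaged over classes when None."""
    cm = _validate_cm(cm)
    if positive is not None:
        row = cm[positive]
        return float(row[positive] / row.sum()) if row.sum() > 0 else float("nan")
    recalls = [cm[c, c] / cm[c].sum() for c in range(cm.shape[0]) if cm[c].sum() > 0]
    return float(np.mean(recalls))


def specificity(cm, positive: int) -> float:
    cm = _validate_cm(cm)
    neg = np.delete(np.arange(cm.shape[0]), positive)
    tn = cm[np.ix_(neg, neg)].sum()
    total_neg = cm[neg].sum()
    return float(tn / total_neg) if total_neg > 0 else float("nan")


def roc_auc(scores, truths) -> float | None:
    """AUC via the Mann-Whitney U statistic, ties counted half.

    Returns ``None`` when only one class is present (AUC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=int)
    if scores.shape != truths.shape:
        raise ValueError("scores and truths must have equal length")
    n1 = int(truths.sum())
    n0 = truths.size - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(scores)                       # average ranks handle ties
    u = ranks[truths == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def macro_ovr_auc(score_matrix, truths) -> float | None:
    """One-vs-rest macro-average AUC for multiclass scores (N, C).

    Classes absent from the truths are skipped; ``None`` if no class has both
    positives and negatives.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    truths = np.asarray(truths, dtype=int)
    aucs = []
    for c in range(score_matrix.shape[1]):
        auc = roc_auc(score_matrix[:, c], (truths == c).astype(int))
        if auc is not None:
            aucs.append(auc)
    return float(np.mean(aucs)) if aucs else None
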