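"""Precision metrics: Pearson r and rank-statistic ROC AUC."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation; zero-variance predictions score 0 with a warning."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        warnings.warn("zero-variance input to pearson_r; recording r=0",
                      stacklevel=2)
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def binary_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic; ties get midranks."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class absent")
    ranks = stats.rankdata(scores)  # midranks on ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def multiclass_ovr_auc(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """One-vs-rest AUC per class; ``scores`` is (n, K) class scores.

    Classes absent from ``labels`` get NaN.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    K = scores.shape[1]
    out = np.full(K, np.nan)
    for k in range(K):
        is_k = (labels == k).astype(int)
        if 0 < is_k.sum() < len(is_k):
            out[k] = binary_auc(is_k, scores[:, k])
    return out
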