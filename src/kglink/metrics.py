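"""Evaluation metrics and the supervised loss.

AUC is the area under the ROC curve (equivalently the tie-aware
Mann–Whitney statistic normalised by ``n_pos · n_neg``); AUPR uses
step-interpolated precision (precision held right-constant between recall
steps), which avoids the optimism of trapezoidal interpolation on PR
curves.  Both delegate to scikit-learn; the surrounding functions add the
input contracts the pipeline relies on.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["compute_roc_auc", "compute_aupr", "bce_loss", "predict_score"]

_EPS = 1e-12


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1 or len(labels) == 0:
        raise ValueError("labels must be a non-empty 1-D array")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute a ranking metric")
    return labels


def compute_roc_auc(scores, labels) -> float:
    """Area under the ROC curve (ties counted 1/2, trapezoidal sweep)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def compute_aupr(scores, labels) -> float:
    """Area under the precision–recall curve, step-interpolated."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def bce_loss(predictions, labels) -> float:
    """Mean binary cross-entropy with scores clipped into (1e-12, 1-1e-12)."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(predictions, dtype=float), _EPS, 1.0 - _EPS)
    if y.shape != p.shape:
        raise ValueError("predictions and labels must align")
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def predict_score(e_m: np.ndarray, e_d: np.ndarray) -> float:
    """Association score σ(e_m · e_d) for one microbe/drug embedding pair."""
    e_m = np.asarray(e_m, dtype=float)
    e_d = np.asarray(e_d, dtype=float)
    if e_m.shape != e_d.shape:
        raise ValueError("embedding lengths differ")
    # clip keeps the result strictly inside (0, 1) in float64
    z = float(np.clip(e_m @ e_d, -30, 30))
    return float(1.0 / (1.0 + np.exp(-z)))
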