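"""Classification performance: AUC, ROC curves, equal-error thresholds.

AUC is computed in its Mann-Whitney form — the fraction of (positive,
negative) pairs where the positive outscores the negative, ties counted as
half a win — which equals the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve


def _check(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present")
    return scores, labels, n_pos, labels.size - n_pos


def auc(scores, labels) -> float:
    """Mann-Whitney AUC; positives are ``labels == True``."""
    scores, labels, n_pos, n_neg = _check(scores, labels)
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_columns(score_matrix, labels) -> np.ndarray:
    """AUC of each column of an (n_samples, n_configs) score matrix."""
    S = np.asarray(score_matrix, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(S, axis=0)
    return (ranks[labels].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """ROC as ordered (1-specificity, sensitivity) points incl. (0,0),(1,1)."""
    scores, labels, _, _ = _check(scores, labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def sensitivity_specificity(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) with the boundary score counted positive."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    sens = float(pred[labels].mean()) if labels.any() else float("nan")
    spec = float((~pred)[~labels].mean()) if (~labels).any() else float("nan")
    return sens, spec


def equal_error_threshold(scores, labels) -> float:
    """Threshold giving (as nearly as possible) equal sensitivity and
    specificity.

    Candidates are midpoints between adjacent unique scores, so the returned
    threshold sits in the middle of a score gap.  Among candidates the one
    minimising |sens - spec| wins; remaining ties are broken by maximal
    sens + spec, then by the smallest threshold.
    """
    scores, labels, _, _ = _check(scores, labels)
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for t in candidates:
        sens, spec = sensitivity_specificity(scores, labels, t)
        key = (abs(sens - spec), -(sens + spec), t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])
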