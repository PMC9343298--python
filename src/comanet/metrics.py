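"""Confusion counts, standard diagnostic metrics, and ROC with the
highest-sensitivity-plus-specificity (Youden) operating point.

"coma" is the positive class throughout: a false negative is a patient
classified as control.  Undefined ratios (zero denominators) are
reported as NaN, never as 0.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .exceptions import ValidationError

POSITIVE_LABEL = "coma"
NEGATIVE_LABEL = "control"


def confusion_counts(y_true, y_pred, positive: str = POSITIVE_LABEL):
    """(TP, FP, TN, FN) with the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("label vectors have different lengths")
    vocab = set(np.unique(y_true)) | set(np.unique(y_pred)) | {positive}
    if len(vocab) > 2:
        raise ValidationError(f"label vocabulary mismatch: {sorted(map(str, vocab))} "
                              "(expected two binary labels)")
    tpos = y_true == positive
    ppos = y_pred == positive
    tp = int(np.sum(tpos & ppos))
    fn = int(np.sum(tpos & ~ppos))
    fp = int(np.sum(~tpos & ppos))
    tn = int(np.sum(~tpos & ~ppos))
    return tp, fp, tn, fn


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """accuracy, sensitivity, specificity, PPV, NPV by the standard formulas."""
    total = tp + fp + tn + fn
    if total == 0:
        raise ValidationError("empty confusion table")
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def roc_auc(y_true, scores, positive: str = POSITIVE_LABEL):
    """(AUC, optimal_threshold).

    AUC is the rank statistic (Mann-Whitney with ties counted half),
    equivalent to the trapezoidal area under the ROC curve.  The optimal
    threshold maximizes sensitivity + specificity over thresholds of the
    form "predict positive when score >= t", candidates being the
    observed scores; ties broken toward the higher threshold.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    candidates = np.unique(scores)[::-1]  # descending: ties -> higher threshold
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred_pos = scores >= t
        sens = np.sum(pred_pos & pos) / n_pos
        spec = np.sum(~pred_pos & ~pos) / n_neg
        j = sens + spec
        if j > best_j:
            best_j, best_t = j, t
    return float(auc), float(best_t)
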