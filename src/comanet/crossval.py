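"""Repeated stratified k-fold evaluation of the per-index classifier.

The reference protocol is tenfold cross-validation repeated 10 times
(100 test folds per MR index).  Folds are class-stratified — with a
29/34 class balance, unstratified folds can produce single-class test
folds that leave sensitivity or specificity undefined — and one plan is
reused across MR indices so that majority voting is well-defined per
subject.  Normalization parameters and model weights for a fold depend
only on that fold's training subjects.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError
from .metrics import POSITIVE_LABEL, confusion_counts, metrics_from_confusion, roc_auc
from .model import CNN3DClassifier
from .volume_io import MinMaxVolumeScaler


def make_folds(labels, k: int = 10, repetitions: int = 10, seed: int = 0) -> pd.DataFrame:
    """Stratified partition plan: one row per (repetition, fold, subject).

    Columns: repetition, fold, position (index into the cohort), role
    is implicit — every subject is in the test fold exactly once per
    repetition.  Deterministic given ``seed``; a fresh shuffle per
    repetition.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ConfigurationError(f"k={k} exceeds the smallest class size {counts.min()}")
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(repetitions)):
        rs = int(child.generate_state(1)[0] % (2 ** 31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            for pos in test_idx:
                rows.append({"repetition": rep, "fold": fold, "position": int(pos)})
    return pd.DataFrame(rows)


def _fold_indices(plan: pd.DataFrame, repetition: int, fold: int, n: int):
    test = plan.query("repetition == @repetition and fold == @fold")["position"].to_numpy()
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def run_cv(X: np.ndarray, y, subject_ids, plan: pd.DataFrame,
           clf_params: dict | None = None, seed: int = 0,
           fold_callback: Callable | None = None,
           verbose: int = 0) -> pd.DataFrame:
    """Train and test a fresh model per (repetition, fold).

    Per fold: fit min-max normalization on the training split only,
    train a fresh network, predict the test split.  Returns one row per
    test prediction: repetition, fold, subject_id, true label, predicted
    label, probability of the positive class.

    ``fold_callback(repetition, fold, clf, scaler, train_idx, test_idx,
    X_train_norm)`` runs after each fold's training, letting the
    visualization stage reuse the trained model without retraining.
    """
    y = np.asarray(y)
    subject_ids = np.asarray(subject_ids)
    n = len(X)
    clf_params = dict(clf_params or {})
    records = []
    for (rep, fold), _ in plan.groupby(["repetition", "fold"]):
        train_idx, test_idx = _fold_indices(plan, rep, fold, n)
        scaler = MinMaxVolumeScaler().fit(X[train_idx])
        x_train = scaler.transform(X[train_idx])
        x_test = scaler.transform(X[test_idx])
        fold_seed = int(np.random.SeedSequence(
            entropy=seed, spawn_key=(rep, fold)).generate_state(1)[0] % (2 ** 31))
        clf = CNN3DClassifier(**clf_params, random_state=fold_seed)
        clf.fit(x_train, y[train_idx])
        proba = clf.predict_proba(x_test)
        pos_col = int(np.argmax(clf.classes_ == POSITIVE_LABEL))
        pred = clf.classes_[np.argmax(proba, axis=1)]
        for i, ti in enumerate(test_idx):
            records.append({"repetition": rep, "fold": fold,
                            "subject_id": subject_ids[ti], "true": y[ti],
                            "pred": pred[i], "p_coma": proba[i, pos_col]})
        if verbose:
            acc = float(np.mean(pred == y[test_idx]))
            print(f"rep {rep} fold {fold}: test accuracy {acc:.2f}")
        if fold_callback is not None:
            fold_callback(rep, fold, clf, scaler, train_idx, test_idx, x_train)
    return pd.DataFrame(records)


def fold_metric_table(fold_results: pd.DataFrame,
                      auc_scores: str = "proba") -> pd.DataFrame:
    """Per-(repetition, fold) metric rows including AUC.

    ``auc_scores="proba"`` ranks by the positive-class probability;
    ``"label"`` ranks by the hard 0/1 prediction, which collapses AUC
    onto balanced accuracy-like behavior.
    """
    if auc_scores not in ("proba", "label"):
        raise ConfigurationError("auc_scores must be 'proba' or 'label'")
    rows = []
    for (rep, fold), grp in fold_results.groupby(["repetition", "fold"]):
        tp, fp, tn, fn = confusion_counts(grp["true"], grp["pred"])
        m = metrics_from_confusion(tp, fp, tn, fn)
        scores = (grp["p_coma"].to_numpy() if auc_scores == "proba"
                  else (grp["pred"] == POSITIVE_LABEL).to_numpy(float))
        try:
            auc, thr = roc_auc(grp["true"], scores)
        except Exception:
            auc, thr = float("nan"), float("nan")
        rows.append({"repetition": rep, "fold": fold, "tp": tp, "fp": fp,
                     "tn": tn, "fn": fn, **m, "auc": auc, "threshold": thr})
    return pd.DataFrame(rows)


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auc")


def summarize_metrics(fold_table: pd.DataFrame, ci_mode: str = "normal") -> pd.DataFrame:
    """mean (SD, 95% CI) per metric over all test folds.

    CI: mean +/- 1.96*SD/sqrt(n_folds) (normal approximation over fold
    values; ``ci_mode="t"`` uses the t quantile instead).  A [0, 1]
    truncated version is reported alongside the raw bounds.
    """
    from scipy import stats

    rows = []
    for metric in METRIC_NAMES:
        vals = fold_table[metric].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        mean = float(np.mean(vals)) if n else float("nan")
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
        q = (stats.t.ppf(0.975, n - 1) if ci_mode == "t" and n > 1 else 1.959963984540054)
        half = q * sd / np.sqrt(n) if n > 1 else float("nan")
        rows.append({"metric": metric, "mean": mean, "sd": sd, "n_folds": n,
                     "ci_low": mean - half, "ci_high": mean + half,
                     "ci_low_clipped": max(mean - half, 0.0) if n > 1 else float("nan"),
                     "ci_high_clipped": min(mean + half, 1.0) if n > 1 else float("nan")})
    return pd.DataFrame(rows)


def per_subject_labels(fold_results: pd.DataFrame) -> pd.DataFrame:
    """Majority label per subject over its repetition-level test predictions.

    Each subject is tested once per repetition; the subject-level label
    is the modal prediction, ties resolved by the mean positive-class
    probability (>= 0.5 predicts the positive class).
    """
    from .metrics import NEGATIVE_LABEL

    rows = []
    for sid, grp in fold_results.groupby("subject_id", sort=False):
        n_pos = int((grp["pred"] == POSITIVE_LABEL).sum())
        n_neg = len(grp) - n_pos
        p_mean = float(grp["p_coma"].mean())
        if n_pos > n_neg:
            label = POSITIVE_LABEL
        elif n_neg > n_pos:
            label = NEGATIVE_LABEL
        else:
            label = POSITIVE_LABEL if p_mean >= 0.5 else NEGATIVE_LABEL
        rows.append({"subject_id": sid, "true": grp["true"].iloc[0],
                     "label": label, "p_coma_mean": p_mean,
                     "n_predictions": len(grp)})
    return pd.DataFrame(rows)
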