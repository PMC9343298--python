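"""Canned desk-scale experiments on the synthetic cohort.

These bundle the full pipeline pieces (generator -> shared fold plan ->
per-index CV -> voting -> difference maps) into single calls at the
desk-scale problem sizes documented in the methods note: 10 controls +
10 patients (8 + 8 for the zero-effect control) on a 64^3 grid, one stratified 2-fold split, and a short
training schedule (6 epochs, batch 5, Adam 2e-4) that stands in for the
full 100-epoch protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crossval import (fold_metric_table, make_folds, per_subject_labels,
                       run_cv, summarize_metrics)
from .fusion import voting_report
from .synthetic import SyntheticConfig, synthesize_cohort_arrays
from .viz import DiffMap, fold_difference_maps, threshold_map

#: short training schedule for desk-scale runs
DESK_TRAIN = dict(epochs=6, batch_size=5, learning_rate=2e-4)


def multi_index_cv(cfg: SyntheticConfig, seed: int, folds: int = 2,
                   repetitions: int = 1, train: dict | None = None,
                   collect_maps: bool = True) -> dict:
    """Run the shared-plan CV for every index of ``cfg``.

    Returns a dict with the config, ground truth, cohort table, fold
    plan, and per-index mean accuracies, per-subject labels/probabilities
    and (optionally) thresholded class-difference maps.
    """
    table, truth, vols = synthesize_cohort_arrays(cfg)
    y = table["class"].to_numpy()
    sids = table["subject_id"].to_numpy()
    plan = make_folds(y, k=folds, repetitions=repetitions, seed=seed)
    out = {"config": cfg, "truth": truth, "table": table, "plan": plan,
           "accuracy": {}, "labels": {}, "probs": {}, "diff": {}}
    for index in cfg.index_names:
        fold_maps: list[np.ndarray] = []

        def cb(rep, fold, clf, scaler, tr, te, xtr, _m=fold_maps, _y=y):
            if collect_maps:
                _m.append(fold_difference_maps(clf, xtr, _y[tr]).data)

        res = run_cv(vols[index], y, sids, plan,
                     clf_params=dict(train or DESK_TRAIN), seed=seed,
                     fold_callback=cb)
        summ = summarize_metrics(fold_metric_table(res))
        out["accuracy"][index] = float(
            summ.set_index("metric").loc["accuracy", "mean"])
        sub = per_subject_labels(res).set_index("subject_id")
        out["labels"][index] = sub["label"]
        out["probs"][index] = sub["p_coma_mean"]
        if collect_maps:
            out["diff"][index] = threshold_map(DiffMap(np.mean(fold_maps, axis=0)))
    return out


def recovery_experiment(seed: int, collect_maps: bool = True) -> dict:
    """Strong-effect parameter-recovery run: five informative indices
    (effect 3 x noise SD) and one pure-noise index (T1)."""
    effects = {n: 3.0 for n in SyntheticConfig().index_names}
    effects["T1"] = 0.0
    cfg = SyntheticConfig(grid_shape=(64, 64, 64), n_controls=10, n_patients=10,
                          effect_size_per_index=effects, seed=seed)
    return multi_index_cv(cfg, seed=seed, collect_maps=collect_maps)


def null_experiment(seed: int) -> dict:
    """Zero-effect control run on a single index."""
    effects = {n: 0.0 for n in SyntheticConfig().index_names}
    cfg = SyntheticConfig(grid_shape=(64, 64, 64), n_controls=8, n_patients=8,
                          effect_size_per_index=effects, index_names=("GM",),
                          seed=seed)
    return multi_index_cv(cfg, seed=seed, collect_maps=False)


def vote_summary(run: dict) -> dict:
    """Fused accuracy and confusion for a multi-index run."""
    labels = pd.DataFrame(run["labels"])
    probs = pd.DataFrame(run["probs"])
    y = run["table"].set_index("subject_id")["class"]
    table, (tp, fp, tn, fn) = voting_report(labels, probs, y)
    return {"accuracy": (tp + tn) / len(table), "tp": tp, "fp": fp,
            "tn": tn, "fn": fn, "table": table}
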