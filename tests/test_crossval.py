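"""Fold planning, leakage hygiene, per-fold records and summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from comanet import make_folds, run_cv
from comanet.crossval import (fold_metric_table, per_subject_labels,
                              summarize_metrics)
from comanet.exceptions import ConfigurationError

COHORT_LABELS = np.array(["control"] * 34 + ["coma"] * 29)


class TestPlan:
    def test_tenfold_on_the_reference_cohort(self):
        plan = make_folds(COHORT_LABELS, k=10, repetitions=1, seed=0)
        sizes = plan.groupby("fold").size()
        assert set(sizes) <= {6, 7}
        for fold, grp in plan.groupby("fold"):
            classes = set(COHORT_LABELS[grp["position"]])
            assert classes == {"coma", "control"}, f"fold {fold} is single-class"

    def test_ten_repetitions_give_one_hundred_folds(self):
        plan = make_folds(COHORT_LABELS, k=10, repetitions=10, seed=0)
        assert len(plan.groupby(["repetition", "fold"])) == 100

    def test_every_subject_tested_once_per_repetition(self):
        plan = make_folds(COHORT_LABELS, k=10, repetitions=3, seed=0)
        counts = plan.groupby(["repetition", "position"]).size()
        assert (counts == 1).all()
        per_subject = plan.groupby("position").size()
        assert (per_subject == 3).all()

    def test_deterministic_and_reshuffled_across_repetitions(self):
        p1 = make_folds(COHORT_LABELS, k=5, repetitions=2, seed=3)
        p2 = make_folds(COHORT_LABELS, k=5, repetitions=2, seed=3)
        assert p1.equals(p2)
        r0 = p1[p1["repetition"] == 0].set_index("position")["fold"]
        r1 = p1[p1["repetition"] == 1].set_index("position")["fold"]
        assert not r0.sort_index().equals(r1.sort_index())

    def test_k_larger_than_class_size_rejected(self):
        with pytest.raises(ConfigurationError):
            make_folds(np.array(["coma"] * 3 + ["control"] * 9), k=4, repetitions=1)


class TestRunCV:
    def test_records_and_normalization_hygiene(self):
        """One record per test prediction, and normalization parameters
        never see the test split: a huge intensity planted in one test
        subject must not leak into that fold's fitted range."""
        rng = np.random.default_rng(0)
        n = 6
        x = rng.random((n, 62, 62, 62), dtype=np.float32)
        y = np.array(["coma", "control"] * 3)
        sids = np.array([f"s{i}" for i in range(n)])
        plan = make_folds(y, k=2, repetitions=1, seed=0)
        spiked = int(plan.query("repetition == 0 and fold == 0")["position"].iloc[0])
        x[spiked, 0, 0, 0] = 1000.0
        seen = {}

        def cb(rep, fold, clf, scaler, tr, te, xtr):
            seen[(rep, fold)] = (scaler.vmax_, tr.copy(), te.copy())

        res = run_cv(x, y, sids, plan, seed=0, fold_callback=cb,
                     clf_params=dict(epochs=1, batch_size=3, learning_rate=1e-3))
        assert len(res) == n
        assert set(res["subject_id"]) == set(sids)
        vmax_f0 = seen[(0, 0)][0]
        assert vmax_f0 < 1000.0, "test-subject intensity leaked into normalization"
        tr, te = seen[(0, 0)][1], seen[(0, 0)][2]
        assert spiked in te and spiked not in tr


class TestSummaries:
    @staticmethod
    def _fake_results():
        rows = []
        preds = {0: ["coma", "coma", "control", "control"],
                 1: ["coma", "control", "coma", "control"]}
        for fold, pred in preds.items():
            for i, p in enumerate(pred):
                rows.append({"repetition": 0, "fold": fold,
                             "subject_id": f"s{fold}{i}",
                             "true": ["coma", "coma", "control", "control"][i],
                             "pred": p, "p_coma": 0.9 if p == "coma" else 0.1})
        return pd.DataFrame(rows)

    def test_fold_confusions_sum_to_pooled_confusion(self):
        res = self._fake_results()
        fm = fold_metric_table(res)
        from comanet import confusion_counts
        pooled = confusion_counts(res["true"], res["pred"])
        assert tuple(fm[["tp", "fp", "tn", "fn"]].sum()) == pooled

    def test_summary_ci_contains_the_mean_and_clips_to_unit_interval(self):
        fm = fold_metric_table(self._fake_results())
        ms = summarize_metrics(fm).set_index("metric")
        for metric, row in ms.iterrows():
            if np.isnan(row["mean"]):
                continue
            assert row["ci_low"] <= row["mean"] <= row["ci_high"]
            assert 0.0 <= row["ci_low_clipped"] <= row["ci_high_clipped"] <= 1.0

    def test_per_subject_majority_and_tie_fallback(self):
        rows = []
        # subject A: coma twice, control once -> coma
        for rep, p in enumerate(["coma", "coma", "control"]):
            rows.append({"repetition": rep, "fold": 0, "subject_id": "A",
                         "true": "coma", "pred": p, "p_coma": 0.6})
        # subject B: 1-1 tie, mean probability below 0.5 -> control
        rows.append({"repetition": 0, "fold": 1, "subject_id": "B",
                     "true": "control", "pred": "coma", "p_coma": 0.55})
        rows.append({"repetition": 1, "fold": 1, "subject_id": "B",
                     "true": "control", "pred": "control", "p_coma": 0.10})
        sub = per_subject_labels(pd.DataFrame(rows)).set_index("subject_id")
        assert sub.loc["A", "label"] == "coma"
        assert sub.loc["B", "label"] == "control"
        assert sub.loc["A", "n_predictions"] == 3
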