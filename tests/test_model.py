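"""Estimator behavior: softmax outputs, inference determinism, training
configuration errors, the plateau LR schedule, and the L2 effect."""

from __future__ import annotations

import numpy as np
import pytest

from comanet import CNN3DClassifier
from comanet.exceptions import ConfigurationError, ShapeError, ValidationError
from comanet.nn import Adam, ReduceLROnPlateau


class TestPrediction:
    def test_probabilities_are_a_softmax(self, tiny_fitted_clf):
        clf, x, _ = tiny_fitted_clf
        p = clf.predict_proba(x)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_volume_gets_identical_rows(self, tiny_fitted_clf):
        clf, x, _ = tiny_fitted_clf
        p = clf.predict_proba(np.stack([x[0], x[0]]))
        assert np.array_equal(p[0], p[1])

    def test_inference_is_independent_of_batch_composition(self, tiny_fitted_clf):
        """BN runs on frozen statistics at inference: a subject's output
        does not change with its batch neighbours, or across calls."""
        clf, x, _ = tiny_fitted_clf
        alone = clf.predict_proba(x[:1])
        together = clf.predict_proba(x)
        assert np.allclose(alone[0], together[0], atol=1e-6)
        assert np.array_equal(clf.predict_proba(x), clf.predict_proba(x))

    def test_grid_mismatch_rejected(self, tiny_fitted_clf):
        clf, _, _ = tiny_fitted_clf
        with pytest.raises(ShapeError):
            clf.predict_proba(np.zeros((1, 32, 32, 32), dtype=np.float32))

    def test_activation_layer_out_of_range(self, tiny_fitted_clf):
        clf, x, _ = tiny_fitted_clf
        with pytest.raises(ValidationError):
            clf.conv_activations(x[:1], layer=7)


class TestFitValidation:
    def test_batch_size_larger_than_cohort(self):
        x = np.zeros((3, 62, 62, 62), dtype=np.float32)
        with pytest.raises(ConfigurationError):
            CNN3DClassifier(batch_size=8).fit(x, ["a", "b", "a"])

    def test_nan_volumes_rejected(self):
        x = np.zeros((2, 62, 62, 62), dtype=np.float32)
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            CNN3DClassifier(batch_size=2).fit(x, ["a", "b"])

    def test_exactly_two_classes_required(self):
        x = np.zeros((3, 62, 62, 62), dtype=np.float32)
        with pytest.raises(ValidationError):
            CNN3DClassifier(batch_size=2, epochs=1).fit(x, ["a", "b", "c"])


class TestPlateauSchedule:
    def test_flat_metric_halves_the_rate_after_patience_epochs(self):
        opt = Adam(1e-3)
        sched = ReduceLROnPlateau(opt, patience=5, factor=0.5)
        sched.step(1.0)  # establishes the best
        for _ in range(4):
            sched.step(1.0)
            assert opt.lr == 1e-3
        sched.step(1.0)  # 5th epoch without progress
        assert opt.lr == pytest.approx(5e-4)

    def test_improvement_resets_patience(self):
        opt = Adam(1e-3)
        sched = ReduceLROnPlateau(opt, patience=2, factor=0.5)
        sched.step(1.0)
        sched.step(0.99)  # no real improvement vs min_delta? 0.99 < 1 - 1e-4 -> improves
        sched.step(1.5)
        sched.step(0.5)  # improvement resets the counter
        sched.step(0.6)
        assert opt.lr == 1e-3

    def test_rate_never_drops_below_the_floor(self):
        opt = Adam(4e-7)
        sched = ReduceLROnPlateau(opt, patience=1, factor=0.5, min_lr=1e-7)
        for _ in range(10):
            sched.step(1.0)
        assert opt.lr == pytest.approx(1e-7)


class TestTraining:
    def test_fit_is_deterministic_given_random_state(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 62, 62, 62), dtype=np.float32)
        y = ["coma", "control", "coma", "control"]
        p = []
        for _ in range(2):
            clf = CNN3DClassifier(epochs=1, batch_size=2, learning_rate=1e-3,
                                  random_state=5)
            clf.fit(x, y)
            p.append(clf.predict_proba(x))
        assert np.array_equal(p[0], p[1])

    def test_history_records_loss_and_lr(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 62, 62, 62), dtype=np.float32)
        clf = CNN3DClassifier(epochs=2, batch_size=2, learning_rate=1e-3,
                              random_state=0)
        clf.fit(x, ["coma", "control", "coma", "control"])
        assert list(clf.history_.columns) == ["epoch", "loss", "lr"]
        assert len(clf.history_) == 2
        assert (clf.history_["lr"] > 0).all()

    def test_l2_shrinks_kernel_norms(self):
        """Same seed and data, with vs without weight decay: the decayed
        network ends with smaller conv/FC kernel norms."""
        rng = np.random.default_rng(0)
        x = rng.random((6, 62, 62, 62), dtype=np.float32)
        y = ["coma", "control"] * 3
        norms = []
        for l2 in (0.0, 0.05):
            clf = CNN3DClassifier(epochs=3, batch_size=3, learning_rate=1e-3,
                                  l2=l2, random_state=7)
            clf.fit(x, y)
            total = sum(float(np.sum(l.params[k] ** 2))
                        for l in clf.network_.layers for k in l.kernel_names)
            norms.append(total)
        assert norms[1] < norms[0]

    def test_weights_roundtrip_through_checkpoint(self, tiny_fitted_clf, tmp_path):
        clf, x, _ = tiny_fitted_clf
        clf.save_weights(tmp_path / "w.npz")
        clone = CNN3DClassifier().load_weights(tmp_path / "w.npz")
        assert np.allclose(clone.predict_proba(x), clf.predict_proba(x), atol=1e-6)
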