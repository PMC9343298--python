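"""Scikit-learn style estimator around the fixed 3D-CNN cascade.

``CNN3DClassifier`` trains one network per MR index on normalized
single-channel volumes and exposes class probabilities plus per-layer
convolutional activations for the visualization maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .architecture import build_network, count_parameters, layer_output_shapes
from .exceptions import ConfigurationError, ShapeError, ValidationError
from .nn import Adam, ReduceLROnPlateau, softmax, softmax_cross_entropy

N_CONV_LAYERS = 6


class CNN3DClassifier(ClassifierMixin, BaseEstimator):
    """Two-class 3D CNN on whole-brain index volumes.

    The architecture is fixed (see :mod:`comanet.architecture`); only the
    training protocol is parametrized.  Defaults follow the published
    protocol: 100 epochs, batch size 8, Adam at 5e-5 with halving after
    5 epochs without training-loss progress, L2 factor 5e-4 on conv/FC
    kernels, categorical cross-entropy.

    Parameters
    ----------
    epochs, batch_size, learning_rate, l2, lr_patience, lr_factor, min_lr
        Training protocol knobs; defaults are the reference protocol.
    bn_eps, bn_momentum
        Batch-norm epsilon and running-statistics momentum.  ``None``
        keeps running statistics as a cumulative average of batch
        statistics, which stays well-calibrated for short runs.
    random_state
        Seeds initialization, batch shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of the two class labels, sorted.
    network_ : the fitted layer cascade.
    history_ : DataFrame with per-epoch ``loss`` and ``lr``.
    input_shape_ : spatial grid the model was fitted on.
    """

    def __init__(self, epochs: int = 100, batch_size: int = 8,
                 learning_rate: float = 5e-5, l2: float = 5e-4,
                 lr_patience: int = 5, lr_factor: float = 0.5,
                 min_lr: float = 1e-7, bn_eps: float = 1e-3,
                 bn_momentum: float | None = None,
                 random_state: int | None = None, verbose: int = 0) -> None:
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.lr_patience = lr_patience
        self.lr_factor = lr_factor
        self.min_lr = min_lr
        self.bn_eps = bn_eps
        self.bn_momentum = bn_momentum
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ fit

    def _validate_volumes(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ShapeError(f"X must be (n_subjects, depth, height, width), got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValidationError("volumes contain NaN or infinite voxels")
        if fitted and tuple(X.shape[1:]) != tuple(self.input_shape_):
            raise ShapeError(f"volume grid {X.shape[1:]} does not match the fitted "
                             f"grid {self.input_shape_}")
        return X

    def fit(self, X, y):
        X = self._validate_volumes(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValidationError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValidationError(f"exactly two classes required, got {list(self.classes_)}")
        n = len(X)
        if self.batch_size > n:
            raise ConfigurationError(f"batch_size {self.batch_size} exceeds the "
                                     f"{n} training samples")
        yi = np.searchsorted(self.classes_, y)
        onehot = np.eye(2, dtype=np.float32)[yi]

        ss = np.random.SeedSequence(self.random_state)
        init_rng, drop_rng, shuffle_rng = (np.random.default_rng(c) for c in ss.spawn(3))
        self.input_shape_ = tuple(X.shape[1:])
        self.network_ = build_network(self.input_shape_, rng=init_rng,
                                      bn_eps=self.bn_eps, bn_momentum=self.bn_momentum,
                                      dropout_rng=drop_rng)
        opt = Adam(self.learning_rate)
        sched = ReduceLROnPlateau(opt, patience=self.lr_patience,
                                  factor=self.lr_factor, min_lr=self.min_lr)
        history = []
        for epoch in range(self.epochs):
            lr_epoch = opt.lr
            perm = shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                xb = X[idx, None]  # add channel axis
                logits = self.network_.forward(xb, training=True)
                loss, dlogits = softmax_cross_entropy(logits, onehot[idx])
                self.network_.backward(dlogits)
                loss += self.network_.l2_penalty_and_grads(self.l2)
                opt.step(self.network_)
                losses.append(loss)
            epoch_loss = float(np.mean(losses))
            history.append({"epoch": epoch, "loss": epoch_loss, "lr": lr_epoch})
            sched.step(epoch_loss)
            if self.verbose:
                print(f"epoch {epoch:3d} loss {epoch_loss:.4f} lr {lr_epoch:.2e}")
        self.history_ = pd.DataFrame(history)
        return self

    # -------------------------------------------------------------- predict

    def _forward_batched(self, X: np.ndarray, collect: list[int] | None = None,
                         batch: int = 8):
        outs, taps = [], []
        for start in range(0, len(X), batch):
            xb = X[start:start + batch, None]
            if collect is None:
                outs.append(self.network_.forward(xb, training=False))
            else:
                o, t = self.network_.forward(xb, training=False, collect=collect)
                outs.append(o)
                taps.append(t)
        out = np.concatenate(outs, axis=0)
        if collect is None:
            return out
        merged = {k: np.concatenate([t[k] for t in taps], axis=0) for k in collect}
        return out, merged

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_volumes(X, fitted=True)
        logits = self._forward_batched(X)
        return softmax(logits.astype(np.float64))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def conv_activations(self, X, layer: int | None = None, batch: int = 8):
        """Post-BN+ELU feature maps of one (1-based) or all conv blocks.

        Returns ``(n, filters, d, h, w)`` for a single layer, or a dict
        ``{layer: maps}`` for ``layer=None``; inference mode throughout.
        """
        X = self._validate_volumes(X, fitted=True)
        taps = self.network_.conv_tap_indices
        if layer is None:
            wanted = list(range(1, N_CONV_LAYERS + 1))
        else:
            if not 1 <= layer <= N_CONV_LAYERS:
                raise ValidationError(f"layer must be in 1..{N_CONV_LAYERS} "
                                      f"(convolutional blocks), got {layer}")
            wanted = [layer]
        collect = [taps[i - 1] for i in wanted]
        _, merged = self._forward_batched(X, collect=collect, batch=batch)
        by_layer = {i: merged[taps[i - 1]] for i in wanted}
        return by_layer if layer is None else by_layer[layer]

    # ------------------------------------------------------------- utility

    def parameter_counts(self) -> tuple[int, int]:
        """(total, trainable) as reported by the fitted network."""
        return self.network_.parameter_counts()

    def save_weights(self, path: str | Path) -> None:
        path = Path(path)
        state = self.network_.state_dict()
        np.savez_compressed(path, **state)
        meta = {"input_shape": list(self.input_shape_),
                "classes": [str(c) for c in self.classes_]}
        path.with_suffix(".json").write_text(json.dumps(meta))

    def load_weights(self, path: str | Path) -> "CNN3DClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        self.input_shape_ = tuple(meta["input_shape"])
        self.classes_ = np.asarray(meta["classes"])
        rng = np.random.default_rng(0)
        self.network_ = build_network(self.input_shape_, rng=rng,
                                      bn_eps=self.bn_eps, bn_momentum=self.bn_momentum)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            self.network_.load_state_dict({k: data[k] for k in data.files})
        self.history_ = pd.DataFrame(columns=["epoch", "loss", "lr"])
        return self


def model_parameter_counts(input_shape: tuple[int, int, int]) -> tuple[int, int]:
    """Closed-form (total, trainable) counts for the cascade on a grid."""
    return count_parameters(input_shape)


def model_output_shapes(input_shape: tuple[int, int, int]):
    """Per-stage spatial shapes and flatten length for a grid."""
    return layer_output_shapes(input_shape)
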