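"""Adam optimizer and reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .network import Sequential


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, net: Sequential) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for layer, name, arr in net.parameters():
            g = layer.grads[name]
            key = id(arr)
            m = self._m.get(key)
            if m is None:
                m = self._m[key] = np.zeros_like(arr)
                self._v[key] = np.zeros_like(arr)
            v = self._v[key]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            arr -= (self.lr * corr) * m / (np.sqrt(v) + self.eps)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate after ``patience`` epochs
    without improvement of the monitored quantity, down to ``min_lr``."""

    def __init__(self, optimizer: Adam, patience: int = 5, factor: float = 0.5,
                 min_lr: float = 1e-7, min_delta: float = 1e-4) -> None:
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.min_delta = min_delta
        self.best = np.inf
        self.wait = 0

    def step(self, metric: float) -> None:
        if metric < self.best - self.min_delta:
            self.best = metric
            self.wait = 0
            return
        self.wait += 1
        if self.wait >= self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.wait = 0
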