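"""Minimal trainable 3D network layers on numpy.

All layers use float32, channels-first layout ``(N, C, D, H, W)`` for
volumetric data and ``(N, U)`` for dense data.  Each layer exposes
``forward(x, training)`` and ``backward(dout)`` and keeps its trainable
parameters in ``self.params`` with matching gradients in ``self.grads``,
so a plain list of layers plus an optimizer is a trainable network.

Convolutions are "valid" (no padding) and implemented as im2col + BLAS
matmul; this is where essentially all compute goes, so the column
matrices are cached between forward and backward and released afterwards.
"""

from __future__ import annotations

import itertools

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer: no parameters, identity pass-through hooks."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        # names of weight matrices subject to L2 (kernels only, never biases/BN)
        self.kernel_names: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. BN running statistics)."""
        return {}


def he_uniform(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv3D(Layer):
    """Valid 3D convolution, kernel ``k``, stride 1.

    im2col keeps the channels-first layout end to end: the column tensor
    is ``(N, C*k^3, P)`` with P the number of output positions, built by
    k^3 contiguous slice copies, and the convolution is one batched GEMM
    per sample — no large transposed copies anywhere.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int = 3, *,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.filters = filters
        self.k = kernel
        fan_in = in_channels * kernel ** 3
        # rows ordered (channel, dz, dy, dx); columns are output filters
        self.params = {
            "W": he_uniform(rng, fan_in, (fan_in, filters)),
            "b": np.zeros(filters, dtype=DTYPE),
        }
        self.kernel_names = ("W",)
        self._col: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        k = self.k
        dp, hp, wp = d - k + 1, h - k + 1, w - k + 1
        p = dp * hp * wp
        col = np.empty((n, c, k ** 3, p), dtype=DTYPE)
        for idx, (i, j, l) in enumerate(itertools.product(range(k), repeat=3)):
            col[:, :, idx, :] = x[:, :, i:i + dp, j:j + hp, l:l + wp].reshape(n, c, p)
        return col.reshape(n, c * k ** 3, p)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        k = self.k
        dp, hp, wp = d - k + 1, h - k + 1, w - k + 1
        col = self._im2col(x)
        out = np.matmul(self.params["W"].T[None], col)  # (N, F, P)
        out += self.params["b"][None, :, None]
        if training:
            self._col = col
            self._in_shape = x.shape
        return out.reshape(n, self.filters, dp, hp, wp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._col is not None and self._in_shape is not None
        n, c, d, h, w = self._in_shape
        k = self.k
        _, f, dp, hp, wp = dout.shape
        p = dp * hp * wp
        dflat = dout.reshape(n, f, p)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        self.grads["W"] = np.matmul(self._col, dflat.transpose(0, 2, 1)).sum(axis=0)
        self._col = None
        dcol = np.matmul(self.params["W"][None], dflat)  # (N, C*k^3, P)
        dcol = dcol.reshape(n, c, k ** 3, p)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for idx, (i, j, l) in enumerate(itertools.product(range(k), repeat=3)):
            dx[:, :, i:i + dp, j:j + hp, l:l + wp] += dcol[:, :, idx].reshape(n, c, dp, hp, wp)
        return dx


class AvgPool3D(Layer):
    """Average pooling with stride equal to the pool size (floor semantics)."""

    def __init__(self, size: int) -> None:
        super().__init__()
        self.s = size
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        s = self.s
        dp, hp, wp = d // s, h // s, w // s
        self._in_shape = x.shape
        if _avgpool_fwd is not None and x.dtype == DTYPE and x.flags.c_contiguous:
            out = np.empty((n, c, dp, hp, wp), dtype=DTYPE)
            _avgpool_fwd(x, out, s)
            return out
        xc = x[:, :, :dp * s, :hp * s, :wp * s]
        return xc.reshape(n, c, dp, s, hp, s, wp, s).mean(axis=(3, 5, 7))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        s = self.s
        dp, hp, wp = d // s, h // s, w // s
        dx = np.empty(self._in_shape, dtype=DTYPE)
        if _avgpool_bwd is not None and dout.dtype == DTYPE:
            _avgpool_bwd(np.ascontiguousarray(dout), dx, s)
            return dx
        dx[:] = 0.0
        g = (dout / s ** 3)[:, :, :, None, :, None, :, None]
        dx[:, :, :dp * s, :hp * s, :wp * s] = np.broadcast_to(
            g, (n, c, dp, s, hp, s, wp, s)).reshape(n, c, dp * s, hp * s, wp * s)
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel/feature axis.

    ``momentum=None`` (default) keeps running statistics as the cumulative
    mean of batch statistics, which stays well-defined for very short
    training runs; a fixed momentum in (0, 1) gives the usual exponential
    moving average.  Running statistics are non-trainable state
    (2 arrays per normalized channel).
    """

    def __init__(self, channels: int, *, eps: float = 1e-3,
                 momentum: float | None = None) -> None:
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=DTYPE),
            "beta": np.zeros(channels, dtype=DTYPE),
        }
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._n_updates = 0
        self._cache = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def _axes_and_bshape(self, x: np.ndarray):
        if x.ndim == 2:
            return (0,), (1, self.channels)
        axes = (0,) + tuple(range(2, x.ndim))
        bshape = [1] * x.ndim
        bshape[1] = self.channels
        return axes, tuple(bshape)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes, bshape = self._axes_and_bshape(x)
        gamma = self.params["gamma"].reshape(bshape)
        beta = self.params["beta"].reshape(bshape)
        fuse = (_bn_stats is not None and x.dtype == DTYPE and x.flags.c_contiguous)
        if training:
            m = x.size // self.channels
            if fuse:
                mu = np.empty(self.channels, dtype=DTYPE)
                msq = np.empty(self.channels, dtype=DTYPE)
                _bn_stats(x.reshape(x.shape[0], self.channels, -1), mu, msq)
                var = np.maximum(msq - mu.astype(np.float64) ** 2, 0.0)
            else:
                mu = x.mean(axis=axes)
                # one-pass second moment instead of x.var (saves a full temp)
                if x.ndim == 2:
                    sq = np.einsum("nc,nc->c", x, x)
                else:
                    xf = x.reshape(x.shape[0], self.channels, -1)
                    sq = np.einsum("ncp,ncp->c", xf, xf)
                var = np.maximum(sq / m - mu * mu, 0.0)
            if self.momentum is None:
                self._n_updates += 1
                self.running_mean += (mu - self.running_mean) / self._n_updates
                self.running_var += (var - self.running_var) / self._n_updates
            else:
                m = self.momentum
                self.running_mean = m * self.running_mean + (1 - m) * mu
                self.running_var = m * self.running_var + (1 - m) * var
            inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
            scale = (self.params["gamma"] * inv_std).astype(DTYPE)
            shift = (self.params["beta"] - mu * scale).astype(DTYPE)
            self._cache = (x, np.asarray(mu, dtype=DTYPE), inv_std, bshape)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            scale = (self.params["gamma"] * inv_std).astype(DTYPE)
            shift = (self.params["beta"] - self.running_mean * scale).astype(DTYPE)
        if fuse and _scale_shift is not None:
            out = np.empty_like(x)
            _scale_shift(x.reshape(x.shape[0], self.channels, -1), scale, shift,
                         out.reshape(x.shape[0], self.channels, -1))
            return out
        return x * scale.reshape(bshape) + shift.reshape(bshape)

    @staticmethod
    def _chan_dot(a: np.ndarray, b: np.ndarray, channels: int) -> np.ndarray:
        if a.ndim == 2:
            return np.einsum("nc,nc->c", a, b)
        return np.einsum("ncp,ncp->c",
                         a.reshape(a.shape[0], channels, -1),
                         b.reshape(b.shape[0], channels, -1))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, mu, inv_std, bshape = self._cache
        self._cache = None
        c = self.channels
        m = dout.size // c
        if _bn_bwd is not None and x.dtype == DTYPE and x.flags.c_contiguous:
            n = x.shape[0]
            dout = np.ascontiguousarray(dout)
            dgamma = np.empty(c, dtype=DTYPE)
            dbeta = np.empty(c, dtype=DTYPE)
            _bn_bwd(x.reshape(n, c, -1), dout.reshape(n, c, -1),
                    mu, inv_std, self.params["gamma"], dgamma, dbeta)
            self.grads["gamma"] = dgamma
            self.grads["beta"] = dbeta
            return dout
        xhat = (x - mu.reshape(bshape)) * inv_std.reshape(bshape)
        dgamma = self._chan_dot(dout, xhat, c)
        dbeta = dout.sum(axis=(0,) if dout.ndim == 2 else
                         (0,) + tuple(range(2, dout.ndim)))
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        # dx = (gamma*inv_std/m) * (m*dout - dbeta - xhat*dgamma), per channel
        dx = m * dout - dbeta.reshape(bshape).astype(DTYPE)
        dx -= xhat * dgamma.reshape(bshape).astype(DTYPE)
        coeff = (self.params["gamma"] * inv_std / m).astype(DTYPE)
        dx *= coeff.reshape(bshape)
        return dx


try:  # fused single-pass ELU kernels; pure-numpy fallback below
    import numba as _nb

    @_nb.njit(cache=True, fastmath=True)
    def _elu_fwd(x, out):  # pragma: no cover - exercised via ELU
        xf = x.ravel()
        of = out.ravel()
        for i in range(xf.size):
            v = xf[i]
            of[i] = v if v > 0 else np.expm1(v)

    @_nb.njit(cache=True, fastmath=True)
    def _elu_bwd(out, dout):  # pragma: no cover - exercised via ELU
        of = out.ravel()
        df = dout.ravel()
        for i in range(of.size):
            v = of[i]
            if v <= 0:
                df[i] *= v + 1.0
    @_nb.njit(cache=True, fastmath=True)
    def _bn_stats(x, mu, sq):  # pragma: no cover - (N, C, P) channel sums
        n_, c_, p_ = x.shape
        for c in range(c_):
            s = 0.0
            s2 = 0.0
            for n in range(n_):
                for p in range(p_):
                    v = x[n, c, p]
                    s += v
                    s2 += v * v
            m = n_ * p_
            mu[c] = s / m
            sq[c] = s2 / m

    @_nb.njit(cache=True, fastmath=True)
    def _scale_shift(x, scale, shift, out):  # pragma: no cover - (N, C, P)
        n_, c_, p_ = x.shape
        for n in range(n_):
            for c in range(c_):
                a = scale[c]
                b = shift[c]
                for p in range(p_):
                    out[n, c, p] = a * x[n, c, p] + b

    @_nb.njit(cache=True, fastmath=True)
    def _avgpool_fwd(x, out, s):  # pragma: no cover
        n_, c_, d_, h_, w_ = out.shape
        inv = 1.0 / (s * s * s)
        for n in range(n_):
            for c in range(c_):
                for i in range(d_):
                    for j in range(h_):
                        for k in range(w_):
                            acc = 0.0
                            for a in range(s):
                                for b in range(s):
                                    for e in range(s):
                                        acc += x[n, c, i * s + a, j * s + b, k * s + e]
                            out[n, c, i, j, k] = acc * inv

    @_nb.njit(cache=True, fastmath=True)
    def _avgpool_bwd(dout, dx, s):  # pragma: no cover
        dx[:] = 0.0
        n_, c_, d_, h_, w_ = dout.shape
        inv = 1.0 / (s * s * s)
        for n in range(n_):
            for c in range(c_):
                for i in range(d_):
                    for j in range(h_):
                        for k in range(w_):
                            g = dout[n, c, i, j, k] * inv
                            for a in range(s):
                                for b in range(s):
                                    for e in range(s):
                                        dx[n, c, i * s + a, j * s + b, k * s + e] = g

    @_nb.njit(cache=True, fastmath=True)
    def _bn_bwd(x, dout, mu, inv_std, gamma, dgamma, dbeta):  # pragma: no cover
        n_, c_, p_ = x.shape
        m = n_ * p_
        for c in range(c_):
            sg = 0.0
            sb = 0.0
            for n in range(n_):
                for p in range(p_):
                    xh = (x[n, c, p] - mu[c]) * inv_std[c]
                    sg += dout[n, c, p] * xh
                    sb += dout[n, c, p]
            dgamma[c] = sg
            dbeta[c] = sb
            coeff = gamma[c] * inv_std[c] / m
            for n in range(n_):
                for p in range(p_):
                    xh = (x[n, c, p] - mu[c]) * inv_std[c]
                    dout[n, c, p] = coeff * (m * dout[n, c, p] - sb - xh * sg)
except ImportError:  # pragma: no cover
    _elu_fwd = None
    _elu_bwd = None
    _bn_bwd = None
    _bn_stats = None
    _scale_shift = None
    _avgpool_fwd = None
    _avgpool_bwd = None


class ELU(Layer):
    """Exponential linear unit, alpha = 1.

    Forward: x for x > 0, expm1(x) otherwise; the derivative on the
    negative side is exp(x) = output + 1, so only the output needs caching.
    With ``inplace=True`` the input buffer is overwritten (safe whenever
    the producing layer does not cache its own output, as BN here).
    """

    def __init__(self, inplace: bool = False) -> None:
        super().__init__()
        self.inplace = inplace

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        can_fuse = _elu_fwd is not None and x.dtype == DTYPE and x.flags.c_contiguous
        out = x if (self.inplace and can_fuse) else np.empty_like(x)
        if can_fuse:
            _elu_fwd(x, out)
        else:
            neg = x < 0
            np.copyto(out, x)
            np.expm1(x, out=out, where=neg)
        self._out = out if training else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = self._out
        self._out = None
        if _elu_bwd is not None and dout.dtype == DTYPE:
            dout = np.ascontiguousarray(dout)
            _elu_bwd(out, dout)
            return dout
        grad = np.where(out > 0, 1.0, out + 1.0).astype(DTYPE)
        return dout * grad


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:  # inference or rate 0: identity
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_units: int, out_units: int, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": he_uniform(rng, in_units, (in_units, out_units)),
            "b": np.zeros(out_units, dtype=DTYPE),
        }
        self.kernel_names = ("W",)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x if training else None
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n
    dlogits = ((p - onehot) / n).astype(DTYPE)
    return float(loss), dlogits
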