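"""Layers with explicit forward/backward passes.

Conventions: activations are ``(N, C, L)`` for temporal layers and ``(N, D)``
after pooling.  ``forward(x, train)`` caches whatever ``backward(dy)`` needs;
``backward`` returns the gradient w.r.t. the input and fills ``self.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """'Same'-padded 1-D convolution with stride, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        fan_in = in_ch * kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(out_ch, in_ch, kernel))
        if bias:
            self.params["b"] = np.zeros(out_ch)
        self._cache = None

    def forward(self, x, train=True):
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        y = np.einsum("nclk,ock->nol", win, self.params["W"], optimize=True)
        if "b" in self.params:
            y = y + self.params["b"][None, :, None]
        self._cache = (x.shape, xp.shape, win)
        return y

    def backward(self, dy):
        x_shape, xp_shape, win = self._cache
        self.grads["W"] = np.einsum("nol,nclk->ock", dy, win, optimize=True)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2))
        dwin = np.einsum("nol,ock->nclk", dy, self.params["W"], optimize=True)
        dxp = np.zeros(xp_shape)
        l_out = dy.shape[2]
        for k in range(self.kernel):
            dxp[:, :, k: k + self.stride * l_out: self.stride] += dwin[:, :, :, k]
        p = self.kernel // 2
        return dxp[:, :, p: p + x_shape[2]]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the batch and time axes."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(ch)
        self.params["beta"] = np.zeros(ch)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * ivar[None, :, None]
        self._cache = (xhat, ivar)
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dy):
        xhat, ivar = self._cache
        m = dy.shape[0] * dy.shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        dxhat = dy * self.params["gamma"][None, :, None]
        # standard batchnorm gradient, vectorized per channel
        term = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / m)
        return term * ivar[None, :, None]


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class GlobalAvgPool1d(Layer):
    """Mean over the temporal axis: (N, C, L) -> (N, C)."""

    def __init__(self):
        super().__init__()
        self._l = None

    def forward(self, x, train=True):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._l, axis=2) / self._l


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.params["b"] = np.zeros(out_dim)
        self._x = None

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"]


class ShortcutA(Layer):
    """Parameter-free residual shortcut: temporal subsampling plus zero-padded
    (or truncated) channels, so the convolution census of a network counts
    only its basic units."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride

    def forward(self, x, train=True):
        y = x[:, :, ::self.stride] if self.stride > 1 else x
        self._x_shape = x.shape
        if self.out_ch == self.in_ch:
            return y
        if self.out_ch > self.in_ch:
            pad = np.zeros((y.shape[0], self.out_ch - self.in_ch, y.shape[2]))
            return np.concatenate([y, pad], axis=1)
        return y[:, : self.out_ch, :]

    def backward(self, dy):
        keep = min(self.in_ch, self.out_ch)
        dx = np.zeros(self._x_shape)
        if self.stride > 1:
            dx[:, :keep, ::self.stride] = dy[:, :keep, :]
        else:
            dx[:, :keep, :] = dy[:, :keep, :]
        return dx
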