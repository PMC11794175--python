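"""Minimal numpy layers with hand-written backward passes.

Small enough to audit, fast enough for desk-scale training on one CPU:
convolutions run as im2col matrix products over
``numpy.lib.stride_tricks.sliding_window_view``.  Every layer follows the
same contract::

    y  = layer.forward(x, train=..., rng=...)
    dx = layer.backward(dy)        # also fills layer.grads

Parameters live in ``layer.params`` (dict of arrays) and their gradients in
``layer.grads`` with matching keys.  All gradients are checked against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2d", "TemporalConv", "SpatialConv3d", "Dense",
    "ReLU", "Dropout", "GlobalAvgPool", "Upsample2x", "Flatten3d",
]


class Layer:
    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float64)


class Conv2d(Layer):
    """2D convolution on (N, C, H, W); zero padding k//2, configurable stride."""

    def __init__(self, c_in, c_out, k=3, stride=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        self.params = {
            "W": _he_init(rng, (c_out, c_in * k * k), c_in * k * k),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=False, rng=None):
        k, s = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(-1, c * k * k)
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, x.shape, (n, ho, wo))
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, (n, ho, wo) = self._cache
        k, s = self.k, self.stride
        p = k // 2
        d2 = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads = {"W": d2.T @ cols, "b": d2.sum(axis=0)}
        dcols = (d2 @ self.params["W"]).reshape(n, ho, wo, self.c_in, k, k)
        dxp = np.zeros((xshape[0], xshape[1], xshape[2] + 2 * p, xshape[3] + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + xshape[2], p:p + xshape[3]]


class TemporalConv(Layer):
    """1D convolution along the T axis of (N, C, T, H, W), mixing channels."""

    def __init__(self, c_in, c_out, k=3, stride=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        self.params = {
            "W": _he_init(rng, (c_out, c_in * k), c_in * k),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=False, rng=None):
        n, c, t, h, w = x.shape
        k, s = self.k, self.stride
        p = k // 2
        xb = x.transpose(0, 3, 4, 1, 2).reshape(n * h * w, c, t)
        xp = np.pad(xb, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s]    # (B, C, To, k)
        to = win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(-1, c * k)
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, (n, c, t, h, w), to)
        out = out.reshape(n, h, w, to, self.c_out)
        return out.transpose(0, 4, 3, 1, 2)

    def backward(self, dy):
        cols, (n, c, t, h, w), to = self._cache
        k, s = self.k, self.stride
        p = k // 2
        d2 = dy.transpose(0, 3, 4, 2, 1).reshape(-1, self.c_out)
        self.grads = {"W": d2.T @ cols, "b": d2.sum(axis=0)}
        dcols = (d2 @ self.params["W"]).reshape(n * h * w, to, c, k)
        dxp = np.zeros((n * h * w, c, t + 2 * p))
        for i in range(k):
            dxp[:, :, i:i + s * to:s] += dcols[:, :, :, i].transpose(0, 2, 1)
        dxb = dxp[:, :, p:p + t]
        return dxb.reshape(n, h, w, c, t).transpose(0, 3, 4, 1, 2)


class SpatialConv3d(Layer):
    """Per-frame 2D convolution on (N, C, T, H, W): T folds into the batch."""

    def __init__(self, c_in, c_out, k=3, stride=1, rng=None):
        self.conv = Conv2d(c_in, c_out, k=k, stride=stride, rng=rng)
        self.params = self.conv.params

    @property
    def grads(self):
        return self.conv.grads

    @grads.setter
    def grads(self, value):
        self.conv.grads = value

    def forward(self, x, train=False, rng=None):
        n, c, t, h, w = x.shape
        self._t = t
        y = self.conv.forward(x.transpose(0, 2, 1, 3, 4).reshape(n * t, c, h, w))
        return y.reshape(n, t, y.shape[1], y.shape[2], y.shape[3]).transpose(0, 2, 1, 3, 4)

    def backward(self, dy):
        n, co, t, ho, wo = dy.shape
        dx = self.conv.backward(dy.transpose(0, 2, 1, 3, 4).reshape(n * t, co, ho, wo))
        c, h, w = dx.shape[1:]
        return dx.reshape(n, t, c, h, w).transpose(0, 2, 1, 3, 4)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {"W": _he_init(rng, (n_out, n_in), n_in), "b": np.zeros(n_out)}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads = {"W": dy.T @ self._x, "b": dy.sum(axis=0)}
        return dy @ self.params["W"]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; active only when train=True and a rng is given."""

    def __init__(self, p=0.15):
        super().__init__()
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in train mode needs a rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GlobalAvgPool(Layer):
    """Mean over all axes after the channel axis: (N, C, ...) -> (N, C)."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1).mean(axis=2)

    def backward(self, dy):
        n_spatial = int(np.prod(self._shape[2:]))
        dy = dy / n_spatial
        return np.broadcast_to(
            dy.reshape(dy.shape[0], dy.shape[1], *([1] * (len(self._shape) - 2))),
            self._shape).copy()


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling on (N, C, H, W)."""

    def forward(self, x, train=False, rng=None):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Flatten3d(Layer):
    """(N, C, T, H, W) -> (N, C*T*H*W)."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)
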