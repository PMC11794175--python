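"""Sequential container and Adam optimizer for the numpy layers."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Sequential", "Adam"]


class Sequential:
    """A straight stack of layers with full backward support.

    ``forward`` can record the activation at a named index (used for
    Grad-CAM); ``backward`` can return the gradient flowing into that index.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None, keep_activation: int | None = None):
        act = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train, rng=rng)
            if keep_activation is not None and i == keep_activation:
                act = x
        return (x, act) if keep_activation is not None else x

    def backward(self, dy, upto: int | None = None):
        """Backprop; if ``upto`` is given, return the gradient arriving at
        the output of layer ``upto`` (without propagating further)."""
        for i in range(len(self.layers) - 1, -1, -1):
            if upto is not None and i == upto:
                return dy
            dy = self.layers[i].backward(dy)
        return dy

    def parameters(self):
        out = []
        for layer in self.layers:
            if layer.params:
                out.append(layer)
        return out

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                state[f"{i}.{k}"] = np.asarray(v)
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = np.asarray(state[f"{i}.{k}"], dtype=float)


class Adam:
    def __init__(self, net: Sequential, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for i, layer in enumerate(net.layers):
            for k, p in layer.params.items():
                self.m[(i, k)] = np.zeros_like(p)
                self.v[(i, k)] = np.zeros_like(p)

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.net.layers):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m = self.m[(i, k)] = self.b1 * self.m[(i, k)] + (1 - self.b1) * g
                v = self.v[(i, k)] = self.b2 * self.v[(i, k)] + (1 - self.b2) * g * g
                mh = m / (1 - self.b1 ** self.t)
                vh = v / (1 - self.b2 ** self.t)
                layer.params[k] = p - self.lr * mh / (np.sqrt(vh) + self.eps)
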