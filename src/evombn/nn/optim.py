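"""SGD with momentum and Adam, over layers exposing params/grads dicts."""

from __future__ import annotations

import numpy as np


class SGDMomentum:
    """Classical momentum: v <- mu v - lr g;  p <- p + v.

    ``lr`` is a plain attribute so schedules can update it between epochs.
    """

    def __init__(self, layers, lr: float = 0.1, momentum: float = 0.9):
        self.layers = list(layers)
        self.lr = lr
        self.momentum = momentum
        self._vel = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                     for lay in self.layers]

    def step(self) -> None:
        for lay, vel in zip(self.layers, self._vel):
            for k, p in lay.params.items():
                g = lay.grads.get(k)
                if g is None:
                    continue
                vel[k] = self.momentum * vel[k] - self.lr * g
                p += vel[k]


class Adam:
    def __init__(self, layers, lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        self.layers = list(layers)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                   for lay in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                   for lay in self.layers]

    def step(self) -> None:
        self.t += 1
        for lay, m, v in zip(self.layers, self._m, self._v):
            for k, p in lay.params.items():
                g = lay.grads.get(k)
                if g is None:
                    continue
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                mhat = m[k] / (1 - self.b1 ** self.t)
                vhat = v[k] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
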