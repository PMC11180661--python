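"""Adam optimiser over (param, grad) array pairs."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    #: magnitudes below this are flushed to zero: the exponential decay of
    #: the moments would otherwise drift into float32 denormals for dead
    #: units, which stalls element-wise kernels by orders of magnitude
    _FLUSH = 1e-30

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            m[np.abs(m) < self._FLUSH] = 0.0
            v[v < self._FLUSH] = 0.0
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
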