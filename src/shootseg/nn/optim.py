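"""Adam optimizer operating on the layers' parameter/gradient dicts."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for l, ms, vs in zip(self.layers, self._m, self._v):
            for k, p in l.params.items():
                g = l.grads[k]
                ms[k] = b1 * ms[k] + (1 - b1) * g
                vs[k] = b2 * vs[k] + (1 - b2) * g * g
                mhat = ms[k] / bc1
                vhat = vs[k] / bc2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
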