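"""Adam optimizer for the layer parameter triples of :mod:`.layers`."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with the Pix2Pix defaults (lr 2e-4, beta1 0.5)."""

    def __init__(self, net, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(v) for name, v, _ in net.params()}
        self.v = {name: np.zeros_like(v) for name, v, _ in net.params()}

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for name, val, grad in self.net.params():
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * grad
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * grad**2
            val -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        self.net.zero_grad()
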