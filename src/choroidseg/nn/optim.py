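"""First-order optimizers for the autodiff parameters."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected first/second moments (Kingma & Ba)."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params: list[Parameter] = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
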