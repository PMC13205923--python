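"""Optimization: AdamW with decoupled weight decay and cosine annealing."""

from __future__ import annotations

import numpy as np

from .core import Parameter


class AdamW:
    """AdamW (decoupled weight decay). Skips frozen parameters entirely."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.params: list[Parameter] = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)


def cosine_annealing_lr(base_lr: float, epoch: int, total_epochs: int, eta_min: float = 0.0) -> float:
    """Learning rate for ``epoch`` (0-based) under cosine annealing to ``eta_min``."""
    if total_epochs <= 1:
        return base_lr
    return eta_min + 0.5 * (base_lr - eta_min) * (1.0 + np.cos(np.pi * epoch / (total_epochs - 1)))
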