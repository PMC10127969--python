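"""Adam optimizer and the cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_annealing_lr(epoch: int, total_epochs: int, lr_init: float,
                        lr_min: float) -> float:
    """Per-epoch cosine schedule from lr_init (epoch 0) to lr_min (last epoch)."""
    if total_epochs <= 1:
        return lr_init
    t = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + np.cos(np.pi * t))
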