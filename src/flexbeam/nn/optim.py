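"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "cosine_lr"]


class Adam:
    """Adam with bias-corrected first/second moments."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``lr0`` at epoch 0 toward 0 at the final epoch."""
    if total_epochs <= 1:
        return lr0
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / (total_epochs - 1)))
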