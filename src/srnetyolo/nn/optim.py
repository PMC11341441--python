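"""SGD with momentum and a cosine learning-rate schedule."""

from __future__ import annotations

import math

__all__ = ["SGD", "cosine_lr"]


class SGD:
    """Stochastic gradient descent with classical momentum.

    Weight decay is applied as L2 regularisation added to the gradient.
    """

    def __init__(self, params, lr=0.01, momentum=0.937, weight_decay=5e-4):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [None] * len(self.params)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self.momentum:
                v = self._velocity[i]
                v = g if v is None else self.momentum * v + g
                self._velocity[i] = v
                g = v
            p.data = p.data - self.lr * g


def cosine_lr(step: int, total_steps: int, lr0: float, lrf: float) -> float:
    """Cosine decay from ``lr0`` down to ``lr0 * lrf`` over ``total_steps``."""
    if total_steps <= 1:
        return lr0
    t = min(step, total_steps - 1) / (total_steps - 1)
    return lr0 * (lrf + (1 - lrf) * 0.5 * (1 + math.cos(math.pi * t)))
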