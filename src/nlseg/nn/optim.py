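"""SGD with Nesterov momentum and polynomial learning-rate decay."""

from __future__ import annotations

import numpy as np

from .layers import Param


def poly_lr(initial_lr: float, step: int, total_steps: int, power: float = 0.9) -> float:
    """Polynomial decay: lr0 * (1 - step/total)^power, floored at 0."""
    frac = min(step / max(total_steps, 1), 1.0)
    return initial_lr * (1.0 - frac) ** power


def clip_grad_norm(params: list[Param], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float((p.grad**2).sum()) for p in params)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


class SGDNesterov:
    """Nesterov-momentum SGD (PyTorch convention): v <- mu v + g; w <- w - lr (g + mu v)."""

    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.99):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        mu = self.momentum
        for p, v in zip(self.params, self._velocity):
            v *= mu
            v += p.grad
            p.value -= self.lr * (p.grad + mu * v)
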