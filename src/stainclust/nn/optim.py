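"""Adadelta optimizer.

Adadelta adapts each parameter's step from running averages of squared
gradients and squared updates, so it is robust to the raw gradient
scale — the property for which it was selected for this model family.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adadelta"]


class Adadelta:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1.0,
        rho: float = 0.95,
        eps: float = 1e-6,
    ):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._sq_grad = [np.zeros_like(p.data) for p in self.params]
        self._sq_delta = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self._sq_grad, self._sq_delta):
            if p.grad is None:
                continue
            g = p.grad
            eg *= self.rho
            eg += (1.0 - self.rho) * g * g
            delta = np.sqrt((ed + self.eps) / (eg + self.eps)) * g
            ed *= self.rho
            ed += (1.0 - self.rho) * delta * delta
            p.data -= self.lr * delta

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
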