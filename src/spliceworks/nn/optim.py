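"""Decoupled-weight-decay Adam (AdamW)."""

from __future__ import annotations

import numpy as np

from .core import Param

__all__ = ["AdamW"]


class AdamW:
    """AdamW with the usual defaults (lr 1e-3, betas (0.9, 0.999), decay 0.01).

    Weight decay is applied directly to the parameter values (decoupled from
    the gradient moments). Frozen parameters (``trainable=False``) are left
    untouched, including decay.
    """

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            mhat = m / bc1
            vhat = v / bc2
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.value)
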