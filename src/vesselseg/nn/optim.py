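"""Optimizers for the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Adam:
    """Adam with bias-corrected first/second moments (no weight decay)."""

    def __init__(
        self,
        params,
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        clipnorm: float | None = None,
    ):
        self.params: list[Tensor] = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.clipnorm = clipnorm
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def _clip_gradients(self):
        total = np.sqrt(
            sum(float(np.sum(p.grad**2)) for p in self.params if p.grad is not None)
        )
        if total > self.clipnorm and total > 0:
            scale = self.clipnorm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale

    def step(self):
        if self.lr == 0.0:
            return
        if self.clipnorm is not None:
            self._clip_gradients()
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
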