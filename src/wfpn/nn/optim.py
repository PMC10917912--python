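"""Optimisation: AdamW with decoupled weight decay and cosine annealing."""

from __future__ import annotations

import math
from typing import List, Sequence

import numpy as np

from .tensor import Tensor


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter).

    Defaults match the training recipe used throughout the package:
    lr 2e-4, weight decay 1e-4.
    """

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 2e-4,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        self.params: List[Tensor] = list(params)
        if not self.params:
            raise ValueError("optimizer received no parameters")
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update


class CosineAnnealingLR:
    """Cosine learning-rate schedule.

    After ``t`` calls to :meth:`step` the rate is

        lr(t) = eta_min + (lr0 - eta_min) * (1 + cos(pi * t / t_max)) / 2

    so it starts at ``lr0`` and reaches ``eta_min`` at ``t = t_max``.
    """

    def __init__(self, optimizer: AdamW, t_max: int, eta_min: float = 0.0):
        if t_max <= 0:
            raise ValueError("t_max must be positive")
        self.optimizer = optimizer
        self.t_max = t_max
        self.eta_min = eta_min
        self.base_lr = optimizer.lr
        self.last_step = 0
        optimizer.lr = self.lr_at(0)

    def lr_at(self, t: int) -> float:
        return self.eta_min + (self.base_lr - self.eta_min) * (
            1.0 + math.cos(math.pi * t / self.t_max)
        ) / 2.0

    def step(self) -> None:
        self.last_step += 1
        self.optimizer.lr = self.lr_at(self.last_step)

    @property
    def current_lr(self) -> float:
        return self.optimizer.lr
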