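"""AdamW: Adam with decoupled weight decay."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["AdamW"]


class AdamW:
    """Adam moments plus weight decay applied directly to the weights.

    Defaults follow the training configuration used throughout this package:
    beta1=0.9, beta2=0.999, eps=1e-7, weight_decay=1e-4.
    """

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.value -= self.lr * (update + self.weight_decay * p.value)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
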