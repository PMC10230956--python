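"""Stochastic gradient descent with momentum and decoupled-free weight decay.

Matches the classic update used for detection/segmentation training:

    v <- momentum * v + grad + weight_decay * w
    w <- w - lr * v
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr < 0:
            raise ValueError("lr must be non-negative")
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
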