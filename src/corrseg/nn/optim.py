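"""Stochastic gradient descent with Nesterov momentum.

The interactive trainer uses lr = 0.01 and momentum = 0.99 with no weight
decay and no learning-rate schedule, so the dataset can keep growing
indefinitely while training runs.
"""

from __future__ import annotations

import numpy as np

from .layers import Param


class SGDNesterov:
    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.99):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        mu, lr = self.momentum, self.lr
        for p, v in zip(self.params, self._vel):
            v *= mu
            v += p.grad
            p.value -= lr * (p.grad + mu * v)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
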