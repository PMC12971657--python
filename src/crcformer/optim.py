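"""Adam optimizer for the autodiff parameters."""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor


class Adam:
    """Adam with bias correction; ``lr`` is mutable between steps so an
    external schedule can drive it."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros(p.data.shape, dtype=DTYPE) for p in self.params]
        self._v = [np.zeros(p.data.shape, dtype=DTYPE) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
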