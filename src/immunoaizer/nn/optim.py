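"""Optimizers for the numpy layer stack.

Weight decay is additive L2 (``grad += wd * param``) in every optimizer,
applied before the moment updates.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, params, lr, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def _decayed(self, p):
        if self.weight_decay:
            return p.grad + self.weight_decay * p.data
        return p.grad

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr, momentum=0.0, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.momentum = momentum
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            g = self._decayed(p)
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = self._decayed(p)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr=0.01, alpha=0.99, eps=1e-8, momentum=0.0, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.alpha, self.eps, self.momentum = alpha, eps, momentum
        self._sq = [np.zeros_like(p.data) for p in self.params]
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, sq, buf in zip(self.params, self._sq, self._buf):
            g = self._decayed(p)
            sq *= self.alpha
            sq += (1 - self.alpha) * g * g
            upd = g / (np.sqrt(sq) + self.eps)
            if self.momentum:
                buf *= self.momentum
                buf += upd
                upd = buf
            p.data -= self.lr * upd
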