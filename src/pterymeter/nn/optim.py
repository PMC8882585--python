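"""Gradient-descent optimizers (RMSprop with momentum, Adam)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["RMSprop", "Adam"]


class _Optimizer:
    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _grad(self, p: Tensor) -> np.ndarray:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        return g


class RMSprop(_Optimizer):
    def __init__(self, params, lr=1e-5, momentum=0.9, alpha=0.99,
                 eps=1e-8, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.momentum = momentum
        self.alpha = alpha
        self.eps = eps
        self.sq = [np.zeros_like(p.data) for p in params]
        self.buf = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, sq, buf in zip(self.params, self.sq, self.buf):
            g = self._grad(p)
            sq *= self.alpha
            sq += (1 - self.alpha) * g * g
            update = g / (np.sqrt(sq) + self.eps)
            if self.momentum:
                buf *= self.momentum
                buf += update
                update = buf
            p.data -= self.lr * update


class Adam(_Optimizer):
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.99,
                 eps=1e-8, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = self._grad(p)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
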