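"""Euclidean optimizers. The Riemannian update for manifold parameters lives
next to the gyroplane bank in :mod:`hyperseg.head`."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["SGD", "Adam"]


class SGD:
    """Stochastic gradient descent with classical momentum.

    The learning rate is passed to :meth:`step` so a schedule (polynomial
    decay) can drive it from outside.
    """

    def __init__(self, params, momentum: float = 0.9):
        self.params = list(params)
        self.momentum = momentum
        self.buffers = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float):
        for p, buf in zip(self.params, self.buffers):
            if p.grad is None:
                continue
            if not np.all(np.isfinite(p.grad)):
                continue
            buf *= self.momentum
            buf += p.grad
            p.data -= lr * buf


class Adam:
    """Adam with bias correction; lr supplied per step for scheduling."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None or not np.all(np.isfinite(p.grad)):
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.data -= lr * mh / (np.sqrt(vh) + self.eps)


def clip_grad_norm(params, max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    params = [p for p in params if isinstance(p, Parameter) and p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total
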