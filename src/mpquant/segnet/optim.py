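"""SGD-with-momentum and Adam, operating in place on model parameters."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "make_optimizer", "clip_grad_norm"]


def clip_grad_norm(model, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.
    """
    total = np.sqrt(sum(float((g**2).sum()) for _, _, g in model.parameters()))
    if total > max_norm > 0:
        scale = max_norm / total
        for _, _, g in model.parameters():
            g *= scale
    return total


class SGD:
    def __init__(self, model, lr: float, momentum: float = 0.9):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self._vel = {name: np.zeros_like(v) for name, v, _ in model.parameters()}

    def step(self) -> None:
        for name, value, grad in self.model.parameters():
            v = self._vel[name]
            v *= self.momentum
            v -= self.lr * grad
            value += v


class Adam:
    def __init__(self, model, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = {name: np.zeros_like(v) for name, v, _ in model.parameters()}
        self._v = {name: np.zeros_like(v) for name, v, _ in model.parameters()}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for name, value, grad in self.model.parameters():
            m, v = self._m[name], self._v[name]
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad**2
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(model, config) -> "SGD | Adam":
    if config.optimizer == "sgd":
        return SGD(model, lr=config.lr, momentum=config.momentum)
    return Adam(model, lr=config.lr)
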