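"""Adaptive-moment optimizers (Adam and its Nesterov variant, Nadam)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "Nadam"]


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _direction(self, i: int, g: np.ndarray) -> np.ndarray:
        m_hat = self.m[i] / (1 - self.b1**self.t)
        v_hat = self.v[i] / (1 - self.b2**self.t)
        return m_hat / (np.sqrt(v_hat) + self.eps)

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * self._direction(i, g)


class Nadam(Adam):
    """Adam with a Nesterov look-ahead on the first moment."""

    def _direction(self, i: int, g: np.ndarray) -> np.ndarray:
        m_hat = self.m[i] / (1 - self.b1 ** (self.t + 1))
        g_hat = g / (1 - self.b1**self.t)
        v_hat = self.v[i] / (1 - self.b2**self.t)
        m_bar = self.b1 * m_hat + (1 - self.b1) * g_hat
        return m_bar / (np.sqrt(v_hat) + self.eps)
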