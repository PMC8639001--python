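"""Rectified Adam (RAdam) optimizer.

RAdam rectifies the variance of the adaptive learning rate in early steps:
while the approximated simple moving average length ``rho_t`` is at most 4,
updates fall back to (momentum-only) SGD; afterwards the Adam step is scaled
by the rectification term ``r_t``. This removes the need for warmup and is
the optimizer used for both GAN networks.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["RAdam"]


class RAdam:
    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.beta2) - 1.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        rho_t = self.rho_inf - 2.0 * t * b2 ** t / (1.0 - b2 ** t)
        bias1 = 1.0 - b1 ** t
        if rho_t > 4.0:
            num = (rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf
            den = (self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t
            r_t = np.sqrt(num / den)
        else:
            r_t = None
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            self.m[i] = b1 * self.m[i] + (1.0 - b1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * g * g
            m_hat = self.m[i] / bias1
            if r_t is not None:
                v_hat = np.sqrt(self.v[i] / (1.0 - b2 ** t)) + self.eps
                p.data = p.data - self.lr * r_t * m_hat / v_hat
            else:
                p.data = p.data - self.lr * m_hat

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]
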