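"""First-order optimizers: SGD, Adam, and LAMB.

LAMB is Adam with a per-parameter (layer-wise) trust ratio
``||w|| / ||update||`` scaling the step, and decoupled weight decay;
it is the default for the pattern classifier.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Optimizer:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam(Optimizer):
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def _adam_update(self, i: int, p: Tensor) -> np.ndarray:
        g = p.grad
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
        mhat = self.m[i] / (1 - self.b1**self.t)
        vhat = self.v[i] / (1 - self.b2**self.t)
        return mhat / (np.sqrt(vhat) + self.eps)

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            upd = self._adam_update(i, p)
            if self.weight_decay:
                upd = upd + self.weight_decay * p.data
            p.data -= self.lr * upd


class Lamb(Adam):
    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            upd = self._adam_update(i, p)
            if self.weight_decay:
                upd = upd + self.weight_decay * p.data
            wnorm = float(np.linalg.norm(p.data))
            unorm = float(np.linalg.norm(upd))
            trust = wnorm / unorm if wnorm > 0 and unorm > 0 else 1.0
            p.data -= self.lr * trust * upd


def make_optimizer(
    name: str,
    params: list[Tensor],
    lr: float,
    weight_decay: float = 0.0,
) -> Optimizer:
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr, weight_decay=weight_decay)
    if name == "lamb":
        return Lamb(params, lr=lr, weight_decay=weight_decay)
    if name == "sgd":
        return SGD(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
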