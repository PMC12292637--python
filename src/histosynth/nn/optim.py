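"""First-order optimizers: SGD, Adam and Adadelta.

Adadelta is included because the diffusion model's main training phase uses
it (learning rate 0.003); Adam drives the autoencoder and the finetuning
phase; plain SGD exists for tests.
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["SGD", "Adam", "Adadelta", "make_optimizer"]


class _Optimizer:
    def __init__(self, params: list[Parameter], lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        raise NotImplementedError


class SGD(_Optimizer):
    def step(self) -> None:
        for p in self.params:
            if p.grad is not None and p.requires_grad:
                p.data -= self.lr * p.grad


class Adam(_Optimizer):
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None or not p.requires_grad:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adadelta(_Optimizer):
    """Adadelta with an explicit learning-rate multiplier on the update."""

    def __init__(self, params, lr=1.0, rho=0.9, eps=1e-6):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.sq_grad = [np.zeros_like(p.data) for p in self.params]
        self.sq_delta = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        rho, eps = self.rho, self.eps
        for i, p in enumerate(self.params):
            if p.grad is None or not p.requires_grad:
                continue
            self.sq_grad[i] = rho * self.sq_grad[i] + (1 - rho) * p.grad**2
            delta = (
                np.sqrt(self.sq_delta[i] + eps) / np.sqrt(self.sq_grad[i] + eps)
            ) * p.grad
            self.sq_delta[i] = rho * self.sq_delta[i] + (1 - rho) * delta**2
            p.data -= self.lr * delta


def make_optimizer(name: str, params, lr: float) -> _Optimizer:
    name = name.lower()
    if name == "sgd":
        return SGD(params, lr)
    if name == "adam":
        return Adam(params, lr)
    if name == "adadelta":
        return Adadelta(params, lr)
    raise ValueError(f"unknown optimizer: {name!r}")
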