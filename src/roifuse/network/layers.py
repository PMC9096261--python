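"""Trainable layers built on the autodiff tape.

Each layer owns its parameters as `Tensor(requires_grad=True)` and
exposes `parameters()`. Weight initialization defaults to He fan-in
scaling; `init="unit_normal"` draws every weight from N(0, 1) instead
(classification heads and deep 3D stacks are numerically fragile under
unit-SD init, so it is opt-in rather than the default).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import DTYPE, Tensor


def _init_weight(rng: np.random.Generator, shape, fan_in: int, init: str) -> np.ndarray:
    if init == "he":
        sd = np.sqrt(2.0 / fan_in)
    elif init == "unit_normal":
        sd = 1.0
    else:
        raise ValueError(f"unknown init {init!r}; use 'he' or 'unit_normal'")
    return (rng.standard_normal(shape) * sd).astype(DTYPE)


class Layer:
    def parameters(self) -> list[Tensor]:
        return []


class Conv3d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator, init: str = "he"):
        k = kernel_size
        fan_in = in_ch * k ** 3
        self.w = Tensor(_init_weight(rng, (out_ch, in_ch, k, k, k), fan_in, init),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 init: str = "he"):
        self.w = Tensor(_init_weight(rng, (in_f, out_f), in_f, init),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_f, DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class BatchNorm(Layer):
    """Batch normalization over all axes but the channel axis."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_ch, DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, DTYPE), requires_grad=True)
        self.running_mean = np.zeros(n_ch, DTYPE)
        self.running_var = np.ones(n_ch, DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.batch_norm(x, self.gamma, self.beta,
                             self.running_mean, self.running_var,
                             training, self.momentum, self.eps)

    def parameters(self):
        return [self.gamma, self.beta]


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
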