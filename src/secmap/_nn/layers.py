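"""Neural building blocks: linear/layer-norm primitives and the Adam
optimizer with cosine-annealed step size."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Module, Parameter, Tensor


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        # Glorot-uniform init
        lim = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Parameter(rng.uniform(-lim, lim, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = ag.tmean(x, axis=-1, keepdims=True)
        centered = x - mu
        var = ag.tmean(centered * centered, axis=-1, keepdims=True)
        inv = ag.power(var + self.eps, -0.5)
        return centered * inv * self.gain + self.shift


class Conv2d(Module):
    """Square-kernel 2D convolution over a (C, P, P) map."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: int,
                 dilation: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        lim = np.sqrt(6.0 / (fan_in + c_out))
        self.weight = Parameter(rng.uniform(-lim, lim, size=(c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.padding, self.dilation)


class Adam:
    """Adam with a cosine-annealed learning rate over `total_steps`."""

    def __init__(self, params, lr: float = 1e-3, total_steps: int | None = None,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr0 = lr
        self.total_steps = total_steps
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    @property
    def lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr0 * 0.5 * (1.0 + np.cos(np.pi * frac))

    def step(self) -> None:
        b1, b2 = self.betas
        lr = self.lr
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + lr * self.weight_decay * p.data  # decoupled
            p.data -= update.astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
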