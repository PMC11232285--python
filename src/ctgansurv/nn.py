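"""Minimal reverse-mode neural-network engine for fully connected GANs.

Layers follow a functional forward/backward contract: ``forward`` returns
``(output, cache)`` and ``backward(cache, grad_out)`` returns the gradient
with respect to the input while accumulating parameter gradients in place.
This lets several forward passes through the same network (as needed for
cycle and identity terms) coexist before a single backward sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Dense",
    "BatchNorm",
    "ReLU",
    "LeakyReLU",
    "Sequential",
    "Residual",
    "Adam",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Dense:
    """Affine layer y = xW + b, He-normal initialised."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        if n_in <= 0 or n_out <= 0:
            raise ValueError(f"invalid Dense dimensions ({n_in}, {n_out})")
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool):
        return x @ self.W.value + self.b.value, x

    def backward(self, cache, dy: np.ndarray):
        x = cache
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class BatchNorm:
    """1-D batch normalisation with running statistics.

    Batch statistics during training; running averages (momentum 0.1,
    eps 1e-5) in inference mode, so generation is batch-composition
    independent.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        return self.gamma.value * xhat + self.beta.value, (xhat, inv_std, training)

    def backward(self, cache, dy: np.ndarray):
        xhat, inv_std, training = cache
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        if not training:
            return dxhat * inv_std
        m = dy.shape[0]
        # standard batch-norm backward: couples samples through mu and var
        return (inv_std / m) * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, training: bool):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, dy: np.ndarray):
        return dy * cache


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        if not 0 <= slope < 1:
            raise ValueError(f"leaky slope must be in [0, 1), got {slope}")
        self.slope = slope

    params: list = []

    def forward(self, x: np.ndarray, training: bool):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, cache, dy: np.ndarray):
        return np.where(cache, dy, self.slope * dy)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, training: bool):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, training)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy: np.ndarray):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(c, dy)
        return dy

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)[0]


class Residual:
    """y = x + inner(x); the skip addition carries no activation."""

    def __init__(self, inner: Sequential):
        self.inner = inner

    @property
    def params(self):
        return self.inner.params

    def forward(self, x: np.ndarray, training: bool):
        h, caches = self.inner.forward(x, training)
        return x + h, caches

    def backward(self, caches, dy: np.ndarray):
        return dy + self.inner.backward(caches, dy)


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
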