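"""Parameters, dense/normalization layers, and the Adam optimizer."""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    """Fan-in-scaled uniform initialization U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Dense:
    """Affine map applied to the last axis: y = x @ W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(fan_in_uniform(rng, (d_in, d_out), d_in))
        self.b = Param(fan_in_uniform(rng, (d_out,), d_in))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        return x @ self.W.value + self.b.value, x

    def backward(self, dout: np.ndarray, cache):
        x = cache
        x2 = x.reshape(-1, x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.W.value.T


def relu(x):
    return np.maximum(x, 0.0)


def relu_grad(dout, x):
    return dout * (x > 0)


class LayerNorm:
    """Layer normalization over the last axis with learned gain/offset."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        return xhat * self.gamma.value + self.beta.value, (xhat, inv)

    def backward(self, dout: np.ndarray, cache):
        xhat, inv = cache
        self.gamma.grad += np.sum(dout * xhat, axis=tuple(range(dout.ndim - 1)))
        self.beta.grad += np.sum(dout, axis=tuple(range(dout.ndim - 1)))
        dxhat = dout * self.gamma.value
        n = xhat.shape[-1]
        return (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * np.mean(dxhat * xhat, axis=-1, keepdims=True)
        ) * inv


def cast_params(params, dtype) -> None:
    """Cast all parameter values/gradients in place (e.g. to float32)."""
    for p in params:
        p.value = p.value.astype(dtype)
        p.grad = p.grad.astype(dtype)


class Adam:
    """Adaptive-moment stochastic gradient descent."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
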