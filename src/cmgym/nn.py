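"""Minimal numpy neural-network layer stack for the Q-learning agents.

Implements exactly what the agents need — 2-D convolution (im2col), ReLU,
flatten, fully-connected layers, mean-squared TD loss and an Adam
optimizer — with deterministic He initialization from a seed and explicit
forward/backward passes.  Weight copies between online and target networks
are plain array copies.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list
    grads: list

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ReLU(Layer):
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


def _im2col(x: np.ndarray, k: int, stride: int):
    """(N, C, H, W) -> (N, out_h*out_w, C*k*k) patches."""
    n, c, h, w = x.shape
    out_h = (h - k) // stride + 1
    out_w = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    shape = (n, c, out_h, out_w, k, k)
    strides = (s0, s1, s2 * stride, s3 * stride, s2, s3)
    patches = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h * out_w, c * k * k)
    return np.ascontiguousarray(cols), out_h, out_w


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = rng.normal(0.0, scale, size=(c_in * kernel * kernel, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        cols, out_h, out_w = _im2col(x, self.k, self.stride)
        self._cols, self._in_shape = cols, x.shape
        self._out_hw = (out_h, out_w)
        out = cols @ self.W + self.b  # (N, L, c_out)
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.c_out, out_h, out_w)

    def backward(self, grad):
        n, _, out_h, out_w = grad.shape
        g = grad.reshape(n, self.c_out, out_h * out_w).transpose(0, 2, 1)  # (N, L, c_out)
        self.grads[0][...] = np.einsum("nlk,nlo->ko", self._cols, g)
        self.grads[1][...] = g.sum(axis=(0, 1))
        dcols = g @ self.W.T  # (N, L, c_in*k*k)
        # scatter-add back to input
        _, c, h, w = self._in_shape
        dx = np.zeros(self._in_shape)
        k, stride = self.k, self.stride
        dpatch = dcols.reshape(n, out_h, out_w, c, k, k)
        for i in range(out_h):
            hi = i * stride
            for j in range(out_w):
                wj = j * stride
                dx[:, :, hi:hi + k, wj:wj + k] += dpatch[:, i, j]
        return dx


class Sequential:
    """Feed-forward stack with shared parameter/gradient lists."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def __call__(self, x):
        return self.forward(x)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)


class Adam:
    """Adam optimizer over a Sequential's parameters."""

    def __init__(self, net: Sequential, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in net.params]
        self.v = [np.zeros_like(p) for p in net.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.net.params, self.net.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
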