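"""Minimal array-backed neural-network building blocks.

Plain numpy layers with explicit forward/backward passes and an Adam
optimizer.  Shapes follow the (batch, groups, channels, length) convention
for the grouped 1-D convolutions and (batch, features) for dense layers.
Randomness (initialization, dropout masks) always flows through an
explicitly passed ``numpy.random.Generator`` so training is reproducible.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: layers expose ``params``/``grads`` lists of arrays kept
    in one-to-one correspondence for the optimizer."""

    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class GroupedConv1d(Layer):
    """1-D convolution applied independently to each of ``groups`` channel
    groups (same padding, stride 1).  Weight shape: (G, C_out, C_in, K)."""

    def __init__(self, groups: int, c_in: int, c_out: int, kernel: int, rng):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, size=(groups, c_out, c_in, kernel))
        self.b = np.zeros((groups, c_out))
        self.K = kernel
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        # x: (B, G, C_in, L)
        B, G, C, L = x.shape
        p = self.K // 2
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (p, p)))
        self._xp, self._L = xp, L
        out = np.zeros((B, G, self.W.shape[1], L))
        for k in range(self.K):
            out += np.einsum("goc,bgcl->bgol", self.W[:, :, :, k],
                             xp[:, :, :, k:k + L])
        out += self.b[None, :, :, None]
        return out

    def backward(self, dout):
        xp, L = self._xp, self._L
        dW = np.zeros_like(self.W)
        dxp = np.zeros_like(xp)
        for k in range(self.K):
            dW[:, :, :, k] = np.einsum("bgol,bgcl->goc", dout,
                                       xp[:, :, :, k:k + L])
            dxp[:, :, :, k:k + L] += np.einsum(
                "goc,bgol->bgcl", self.W[:, :, :, k], dout)
        self.grads[0][...] = dW
        self.grads[1][...] = dout.sum(axis=(0, 3))
        p = self.K // 2
        return dxp[:, :, :, p:p + L] if p else dxp

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Max pooling over the last (length) axis, stride = pool size."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train=False, rng=None):
        *lead, L = x.shape
        n = L // self.size
        xv = x[..., :n * self.size].reshape(*lead, n, self.size)
        self._arg = xv.argmax(axis=-1)
        self._shape = x.shape
        return xv.max(axis=-1)

    def backward(self, dout):
        *lead, n = dout.shape
        dx = np.zeros(self._shape)
        dxv = dx[..., :n * self.size].reshape(*lead, n, self.size)
        np.put_along_axis(dxv, self._arg[..., None], dout[..., None], axis=-1)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng, zero_init: bool = False):
        super().__init__()
        if zero_init:
            self.W = np.zeros((n_out, n_in))
        else:
            self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.grads[0][...] = dout.T @ self._x
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-likelihood of integer ``targets`` under ``probs``."""
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(targets)), targets] + eps)))


def softmax_ce_grad(probs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the logits."""
    g = probs.copy()
    g[np.arange(len(targets)), targets] -= 1.0
    return g / len(targets)


class Adam:
    """Adaptive moment estimation over a flat list of parameter arrays."""

    def __init__(self, params: list, grads: list, lr: float = 0.02,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
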