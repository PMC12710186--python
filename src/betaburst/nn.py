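"""Minimal 1-D convolutional network with manual backpropagation.

Self-contained building blocks (convolution via im2col, batch
normalization, ReLU, max pooling, inverted dropout, global average
pooling, a dense sigmoid head) and an Adam optimizer, all in numpy.
Shapes follow the (batch, channels, length) convention.  Every source of
randomness (initialization, dropout) is drawn from the generator handed
in by the caller, so a fixed seed reproduces training bit-for-bit.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """Same-length 1-D convolution (odd kernel, zero padding)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel length must be odd")
        std = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.kernel = kernel
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (B, C_in, L, K) view of all kernel-sized patches
        self._cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        out = np.tensordot(self._cols, self.W, axes=([1, 3], [1, 2]))
        self._in_len = x.shape[2]
        return out.transpose(0, 2, 1) + self.b[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = np.tensordot(dout, self._cols, axes=([0, 2], [0, 2]))
        self.db[...] = dout.sum(axis=(0, 2))
        B, _, L = dout.shape
        pad = self.kernel // 2
        g = np.tensordot(dout.transpose(0, 2, 1), self.W, axes=([2], [0]))  # (B,L,Cin,K)
        dxp = np.zeros((B, self.W.shape[1], L + 2 * pad), dtype=DTYPE)
        for k in range(self.kernel):
            dxp[:, :, k : k + L] += g[:, :, :, k].transpose(0, 2, 1)
        return dxp[:, :, pad : pad + self._in_len]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm1d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._invstd[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L = dout.shape
        n = B * L
        self.dgamma[...] = np.sum(dout * self._xhat, axis=(0, 2))
        self.dbeta[...] = np.sum(dout, axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        s1 = dxhat.sum(axis=(0, 2))[None, :, None]
        s2 = np.sum(dxhat * self._xhat, axis=(0, 2))[None, :, None]
        return (self._invstd[None, :, None] / n) * (
            n * dxhat - s1 - self._xhat * s2
        )

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Pool size 2; an odd trailing sample is dropped."""

    def forward(self, x, train):
        B, C, L = x.shape
        self._in_len = L
        L2 = L // 2
        x4 = x[:, :, : 2 * L2].reshape(B, C, L2, 2)
        self._argmax = x4.argmax(axis=3)
        return x4.max(axis=3)

    def backward(self, dout):
        B, C, L2 = dout.shape
        dx4 = np.zeros((B, C, L2, 2), dtype=DTYPE)
        np.put_along_axis(dx4, self._argmax[..., None], dout[..., None], axis=3)
        dx = dx4.reshape(B, C, 2 * L2)
        if self._in_len > 2 * L2:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, self._in_len - 2 * L2)))
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout fraction must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._in_len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._in_len, axis=2) / self._in_len


class Dense(Layer):
    """Final linear head to a single logit; zero-initialized so an
    untrained network outputs probability exactly 0.5."""

    def __init__(self, c_in: int):
        self.W = np.zeros(c_in, dtype=DTYPE)
        self.b = np.zeros(1, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b[0]

    def backward(self, dout):
        self.dW[...] = dout @ self._x
        self.db[...] = dout.sum()
        return np.outer(dout, self.W)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params())
        for p, s in zip(self.params(), state[:n]):
            p[...] = s
        extra = iter(state[n:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(z: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Mean weighted binary cross-entropy and its gradient wrt logits."""
    loss_i = np.logaddexp(0.0, z) - y * z
    loss = float(np.mean(w * loss_i))
    dz = w * (sigmoid(z) - y) / len(z)
    return loss, dz
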