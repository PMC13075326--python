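"""Minimal NumPy layer library with exact backpropagation.

No deep-learning framework ships in the target environment, so the 1D
residual network is built on these hand-verified layers. Tensors are
channels-last float32: signals are (batch, time, channels). Each layer
caches what its backward pass needs; parameter gradients accumulate in
``grads`` aligned with ``params``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def conv_out_len(L: int, k: int, stride: int, pad: int) -> int:
    return (L + 2 * pad - k) // stride + 1


class Conv1d(Layer):
    """1D convolution via im2col + BLAS matmul. Weight: (C_out, C_in, k)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, k // 2
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / (c_in * k))  # He initialization
        self.params = {
            "W": rng.normal(0, std, (c_out, c_in, k)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        sw = sliding_window_view(xp, self.k, axis=1)[:, :: self.stride]  # N,Lout,C,k
        Lout = sw.shape[1]
        col = np.ascontiguousarray(sw).reshape(N * Lout, C * self.k)
        Wm = self.params["W"].reshape(self.c_out, C * self.k)
        y = col @ Wm.T + self.params["b"]
        self._cache = (col, (N, L, Lout))
        return y.reshape(N, Lout, self.c_out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        col, (N, L, Lout) = self._cache
        gflat = gy.reshape(N * Lout, self.c_out)
        Wm = self.params["W"].reshape(self.c_out, self.c_in * self.k)
        self.grads["W"] = (gflat.T @ col).reshape(self.params["W"].shape)
        self.grads["b"] = gflat.sum(axis=0)
        gcol = (gflat @ Wm).reshape(N, Lout, self.c_in, self.k)
        gxp = np.zeros((N, L + 2 * self.pad, self.c_in), dtype=np.float32)
        for j in range(self.k):
            idx = np.arange(Lout) * self.stride + j
            gxp[:, idx, :] += gcol[:, :, :, j]
        return gxp[:, self.pad : self.pad + L, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(c, dtype=np.float32),
            "beta": np.zeros(c, dtype=np.float32),
        }
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std.astype(np.float32), train, x.shape[0] * x.shape[1])
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, m = self._cache
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = gy.sum(axis=(0, 1))
        gxhat = gy * self.params["gamma"]
        if not train:
            return gxhat * inv_std
        return (
            inv_std
            / m
            * (m * gxhat - gxhat.sum(axis=(0, 1)) - xhat * (gxhat * xhat).sum(axis=(0, 1)))
        ).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)


class MaxPool1d(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)), constant_values=-np.inf)
        sw = sliding_window_view(xp, self.k, axis=1)[:, :: self.stride]  # N,Lout,C,k
        arg = sw.argmax(axis=3)
        y = np.take_along_axis(sw, arg[..., None], axis=3)[..., 0]
        self._cache = (arg, (N, L, sw.shape[1], C))
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        arg, (N, L, Lout, C) = self._cache
        gxp = np.zeros((N, L + 2 * self.pad, C), dtype=np.float32)
        pos = np.arange(Lout)[None, :, None] * self.stride + arg  # index into padded axis
        n_idx = np.arange(N)[:, None, None]
        c_idx = np.arange(C)[None, None, :]
        np.add.at(gxp, (n_idx, pos, c_idx), gy)
        return gxp[:, self.pad : self.pad + L, :]


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.repeat(gy[:, None, :], self._L, axis=1) / self._L


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, he: bool = True):
        super().__init__()
        std = np.sqrt((2.0 if he else 1.0) / d_in)
        self.params = {
            "W": rng.normal(0, std, (d_in, d_out)).astype(np.float32),
            "b": np.zeros(d_out, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"].T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with bias correction (defaults match the common framework values)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        slot = 0
        for layer in layers:
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    slot += 1
                    continue
                m = self._m.setdefault(slot, np.zeros_like(p))
                v = self._v.setdefault(slot, np.zeros_like(p))
                m += (1 - self.beta1) * (g - m)
                v += (1 - self.beta2) * (g * g - v)
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                slot += 1
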