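"""Feed-forward building blocks with explicit backward passes.

All layers cache what they need during forward and expose
``backward(dy) -> dx`` accumulating parameter gradients in-place.  Arrays are
float32; initialisation follows the fan-in uniform convention.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _uniform(rng, shape, fan_in):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(_uniform(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Conv1d:
    """1-D convolution on (B, T, C) with 'same'-style padding so that
    T_out = T // stride (T must be divisible by stride).

    Channels-last layout lets each kernel tap run as a batched GEMM on a
    view of the padded input — no im2col materialisation."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        # per-tap weight (K, C_in, C_out)
        self.W = Parameter(_uniform(rng, (kernel, c_in, c_out), c_in * kernel))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def _geometry(self, T):
        t_out = T // self.stride
        pad_l = (self.kernel - 1) // 2
        pad_r = max(0, (t_out - 1) * self.stride + self.kernel - T - pad_l)
        return t_out, pad_l, pad_r

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, T, C = x.shape
        if T % self.stride:
            raise ValueError("input length not divisible by stride")
        t_out, pad_l, pad_r = self._geometry(T)
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        y = np.broadcast_to(self.b.value, (B, t_out, self.c_out)).copy()
        s = self.stride
        for k in range(self.kernel):
            xs = xp[:, k : k + (t_out - 1) * s + 1 : s, :]
            y += xs @ self.W.value[k]
        self._cache = (xp, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        B, T, C = x_shape
        t_out, pad_l, _ = self._geometry(T)
        s = self.stride
        dxp = np.zeros_like(xp)
        dy2 = dy.reshape(-1, self.c_out)
        self.b.grad += dy2.sum(axis=0)
        for k in range(self.kernel):
            sl = slice(k, k + (t_out - 1) * s + 1, s)
            xs = xp[:, sl, :]
            self.W.grad[k] += xs.reshape(-1, C).T @ dy2
            dxp[:, sl, :] += dy @ self.W.value[k].T
        return dxp[:, pad_l : pad_l + T, :]


class BatchNorm1d:
    """Per-channel normalization over (B, T) for inputs shaped (B, T, C)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        # batch-norm backward (training statistics)
        term = (
            dxhat
            - dxhat.mean(axis=(0, 1), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 1), keepdims=True)
        )
        return term * inv
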