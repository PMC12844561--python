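"""LSTM layers with numba-compiled time recurrences.

The input projection x @ Wx + b for all timesteps is hoisted out of the loop
as one large matmul; the compiled kernels carry only the recurrent part
(h @ Wh, the gate nonlinearities, and their reverse-mode counterparts).
Gate layout along the 4H axis is [input, forget, cell, output].
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .layers import Parameter, _uniform


@njit(inline="always")
def _ftanh(x):
    """Clamped Pade(7,6) tanh: |error| < 2e-6 on the clamp range, avoids
    libm calls in the recurrent inner loop."""
    if x > 4.97:
        return 1.0
    if x < -4.97:
        return -1.0
    x2 = x * x
    p = x * (135135.0 + x2 * (17325.0 + x2 * (378.0 + x2)))
    q = 135135.0 + x2 * (62370.0 + x2 * (3150.0 + x2 * 28.0))
    return p / q


@njit(inline="always")
def _fsigmoid(x):
    return 0.5 * (1.0 + _ftanh(0.5 * x))


@njit(cache=True, fastmath=True)
def _lstm_forward_kernel(xw, Wh):
    """xw: (T, B, 4H) pre-activations from the input projection; overwritten
    with post-activation gates.  Returns (h, c) each (T, B, H)."""
    T, B, H4 = xw.shape
    H = H4 // 4
    h = np.zeros((T, B, H), dtype=xw.dtype)
    c = np.zeros((T, B, H), dtype=xw.dtype)
    hprev = np.zeros((B, H), dtype=xw.dtype)
    cprev = np.zeros((B, H), dtype=xw.dtype)
    for t in range(T):
        g = xw[t] + np.dot(hprev, Wh)
        for b in range(B):
            for j in range(H):
                i_ = _fsigmoid(g[b, j])
                f_ = _fsigmoid(g[b, H + j])
                z_ = _ftanh(g[b, 2 * H + j])
                o_ = _fsigmoid(g[b, 3 * H + j])
                cc = f_ * cprev[b, j] + i_ * z_
                g[b, j] = i_
                g[b, H + j] = f_
                g[b, 2 * H + j] = z_
                g[b, 3 * H + j] = o_
                c[t, b, j] = cc
                h[t, b, j] = o_ * _ftanh(cc)
        xw[t] = g
        hprev = h[t]
        cprev = c[t]
    return h, c


@njit(cache=True, fastmath=True)
def _lstm_backward_kernel(gates, c, hT, WhT, dh_out):
    """Reverse-mode pass.  gates: (T,B,4H) post-activation; hT: (T,H,B)
    transposed hidden states; returns (dG pre-activation gate grads
    (T,B,4H), dWh (H,4H))."""
    T, B, H4 = gates.shape
    H = H4 // 4
    dG = np.zeros((T, B, H4), dtype=gates.dtype)
    dWh = np.zeros((H, H4), dtype=gates.dtype)
    dh = np.zeros((B, H), dtype=gates.dtype)
    dc = np.zeros((B, H), dtype=gates.dtype)
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for j in range(H):
                dhb = dh[b, j] + dh_out[t, b, j]
                i_ = gates[t, b, j]
                f_ = gates[t, b, H + j]
                z_ = gates[t, b, 2 * H + j]
                o_ = gates[t, b, 3 * H + j]
                tc = _ftanh(c[t, b, j])
                dcb = dc[b, j] + dhb * o_ * (1.0 - tc * tc)
                cp = c[t - 1, b, j] if t > 0 else 0.0
                dG[t, b, j] = dcb * z_ * i_ * (1.0 - i_)
                dG[t, b, H + j] = dcb * cp * f_ * (1.0 - f_)
                dG[t, b, 2 * H + j] = dcb * i_ * (1.0 - z_ * z_)
                dG[t, b, 3 * H + j] = dhb * tc * o_ * (1.0 - o_)
                dc[b, j] = dcb * f_
        dh = np.dot(dG[t], WhT)
        if t > 0:
            dWh += np.dot(hT[t - 1], dG[t])
    return dG, dWh


class LSTM:
    """Unidirectional LSTM over (T, B, I) -> (T, B, H).

    ``reverse=True`` processes time back-to-front (output re-reversed so the
    time axis is preserved)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        self.n_in, self.hidden, self.reverse = n_in, hidden, reverse
        self.Wx = Parameter(_uniform(rng, (n_in, 4 * hidden), hidden))
        self.Wh = Parameter(_uniform(rng, (hidden, 4 * hidden), hidden))
        self.b = Parameter(np.zeros(4 * hidden, dtype=np.float32))
        # forget-gate bias 1: standard recurrent-net initialisation
        self.b.value[hidden : 2 * hidden] = 1.0

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self.reverse:
            x = x[::-1]
        x = np.ascontiguousarray(x, dtype=np.float32)
        T, B, _ = x.shape
        xw = (x.reshape(T * B, -1) @ self.Wx.value + self.b.value).reshape(
            T, B, 4 * self.hidden
        )
        h, c = _lstm_forward_kernel(xw, self.Wh.value)
        self._cache = (x, xw, h, c)  # xw now holds post-activation gates
        return h[::-1] if self.reverse else h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, gates, h, c = self._cache
        if self.reverse:
            dy = dy[::-1]
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        WhT = np.ascontiguousarray(self.Wh.value.T)
        hT = np.ascontiguousarray(h.transpose(0, 2, 1))
        dG, dWh = _lstm_backward_kernel(gates, c, hT, WhT, dy)
        T, B, _ = x.shape
        dG2 = dG.reshape(T * B, -1)
        x2 = x.reshape(T * B, -1)
        self.Wx.grad += x2.T @ dG2
        self.Wh.grad += dWh
        self.b.grad += dG2.sum(axis=0)
        dx = (dG2 @ self.Wx.value.T).reshape(x.shape)
        return dx[::-1] if self.reverse else dx


class BiLSTM:
    """Bidirectional LSTM: forward and reverse cells, outputs concatenated
    along the feature axis -> (T, B, 2H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(n_in, hidden, rng, reverse=False)
        self.bwd = LSTM(n_in, hidden, rng, reverse=True)
        self.hidden = hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.concatenate(
            [self.fwd.forward(x, train), self.bwd.forward(x, train)], axis=-1
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.hidden
        return self.fwd.backward(dy[..., :H]) + self.bwd.backward(dy[..., H:])
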