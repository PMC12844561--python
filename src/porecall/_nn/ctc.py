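"""Connectionist temporal classification: log-space forward-backward.

Class 0 is the blank.  The loss for one chunk is
``-log sum_paths prod_t p_t(path_t)`` over all blank-augmented frame paths
that collapse (merge repeats, drop blanks) to the target; the gradient with
respect to the pre-softmax logits is ``softmax - gamma`` where ``gamma`` is
the per-frame posterior over classes given the target.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30


def ctc_feasible(n_frames: int, labels: np.ndarray) -> bool:
    """A target fits in T frames iff len + number of adjacent repeats <= T."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return True
    repeats = int(np.sum(labels[1:] == labels[:-1]))
    return labels.size + repeats <= n_frames


@njit(cache=True, fastmath=True)
def _ctc_kernel(logp, labels):
    """logp: (T, C) log-probabilities; labels: (L,) ints in 1..C-1.
    Returns (loss, gamma (T, C)).

    Forward-backward runs in probability space with per-timestep rescaling
    (the classical scaled-HMM recursion), which avoids log-sum-exp in the
    inner loop; the log-likelihood is recovered from the scale factors."""
    T, C = logp.shape
    L = labels.size
    S = 2 * L + 1

    ext = np.zeros(S, dtype=np.int64)  # blanks at even s
    for i in range(L):
        ext[2 * i + 1] = labels[i]
    p = np.exp(logp)

    alpha = np.zeros((T, S))
    log_scale = 0.0
    alpha[0, 0] = p[0, 0]
    if S > 1:
        alpha[0, 1] = p[0, ext[1]]
    c0 = alpha[0].sum()
    alpha[0] /= c0
    log_scale += np.log(c0)
    for t in range(1, T):
        ct = 0.0
        for s in range(S):
            a = alpha[t - 1, s]
            if s >= 1:
                a += alpha[t - 1, s - 1]
            if s >= 2 and ext[s] != 0 and ext[s] != ext[s - 2]:
                a += alpha[t - 1, s - 2]
            a *= p[t, ext[s]]
            alpha[t, s] = a
            ct += a
        if ct <= 0.0:
            return np.inf, np.zeros((T, C))
        for s in range(S):
            alpha[t, s] /= ct
        log_scale += np.log(ct)

    tail = alpha[T - 1, S - 1]
    if S > 1:
        tail += alpha[T - 1, S - 2]
    if tail <= 0.0:
        return np.inf, np.zeros((T, C))
    loglik = log_scale + np.log(tail)

    beta = np.zeros((T, S))
    beta[T - 1, S - 1] = p[T - 1, 0]
    if S > 1:
        beta[T - 1, S - 2] = p[T - 1, ext[S - 2]]
    bt = beta[T - 1].sum()
    beta[T - 1] /= bt
    for t in range(T - 2, -1, -1):
        dt = 0.0
        for s in range(S):
            b = beta[t + 1, s]
            if s + 1 < S:
                b += beta[t + 1, s + 1]
            if s + 2 < S and ext[s + 2] != 0 and ext[s + 2] != ext[s]:
                b += beta[t + 1, s + 2]
            b *= p[t, ext[s]]
            beta[t, s] = b
            dt += b
        if dt <= 0.0:
            return np.inf, np.zeros((T, C))
        for s in range(S):
            beta[t, s] /= dt

    # per-frame state posterior sums to 1, so normalising row-wise removes
    # all scale factors: gamma[t,c] = sum_{s: ext[s]=c} post[t,s]
    gamma = np.zeros((T, C))
    for t in range(T):
        norm = 0.0
        for s in range(S):
            e = p[t, ext[s]]
            g = alpha[t, s] * beta[t, s] / e if e > 0 else 0.0
            norm += g
        if norm <= 0.0:
            return np.inf, np.zeros((T, C))
        for s in range(S):
            e = p[t, ext[s]]
            if e > 0:
                gamma[t, ext[s]] += alpha[t, s] * beta[t, s] / (e * norm)
    return -loglik, gamma


def ctc_loss_grad(logp: np.ndarray, labels: np.ndarray):
    """Loss (nats) and per-frame class posteriors for one chunk.

    ``logp`` is a (T, C) log-probability matrix; ``labels`` integer classes
    in 1..C-1.  Returns (loss, gamma); the logit gradient of the loss is
    ``exp(logp) - gamma``.  Infeasible targets give loss = +inf.
    """
    labels = np.asarray(labels, dtype=np.int64)
    logp = np.asarray(logp, dtype=np.float64)
    if not ctc_feasible(logp.shape[0], labels):
        return np.inf, np.zeros_like(logp)
    if labels.size == 0:
        # only the all-blank path remains
        loss = -float(logp[:, 0].sum())
        gamma = np.zeros_like(logp)
        gamma[:, 0] = 1.0
        return loss, gamma
    return _ctc_kernel(logp, labels)
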