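"""Numerical kernels for the Gaussian hidden Markov model.

Scaled forward-backward and Viterbi recursions, JIT-compiled with numba.
Emission likelihoods enter as per-frame log densities and are rescaled by
their per-frame maximum before exponentiation, so arbitrarily unlikely
observations (e.g. near-noiseless traces with tiny emission SDs) do not
underflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward", "viterbi"]


@njit(cache=True)
def forward_backward(log_b, trans, start):
    """E-step quantities for one trace.

    Parameters: log emission densities (T, K), transition matrix (K, K),
    initial distribution (K,). Returns (gamma, xi_sum, loglik).
    """
    T, K = log_b.shape
    b = np.empty((T, K))
    shift = np.empty(T)
    for t in range(T):
        m = log_b[t, 0]
        for k in range(1, K):
            if log_b[t, k] > m:
                m = log_b[t, k]
        shift[t] = m
        for k in range(K):
            b[t, k] = np.exp(log_b[t, k] - m)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = start[k] * b[0, k]
        s += alpha[0, k]
    if s <= 0.0:
        s = 1e-300
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * trans[i, j]
            a *= b[t, j]
            alpha[t, j] = a
            s += a
        if s <= 0.0:
            s = 1e-300
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            a = 0.0
            for j in range(K):
                a += trans[i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = a / c[t + 1]

    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            s += gamma[t, k]
        if s > 0.0:
            for k in range(K):
                gamma[t, k] /= s

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += (alpha[t, i] * trans[i, j] * b[t + 1, j]
                                 * beta[t + 1, j] / c[t + 1])

    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t]) + shift[t]
    return gamma, xi_sum, loglik


@njit(cache=True)
def viterbi(log_b, trans, start):
    """Most probable state path (global decoding) and its log probability."""
    T, K = log_b.shape
    log_trans = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            log_trans[i, j] = np.log(trans[i, j]) if trans[i, j] > 0 else -1e300
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = (np.log(start[k]) if start[k] > 0 else -1e300) + log_b[0, k]
    for t in range(1, T):
        for j in range(K):
            best = -1e301
            arg = 0
            for i in range(K):
                v = delta[t - 1, i] + log_trans[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + log_b[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -1e301
    for k in range(K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            path[T - 1] = k
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
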