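"""Inner dynamic-programming recursions for the HMM.

The forward pass runs in scaled linear space (per-step normalisation with the
log of the scale accumulated), the Viterbi pass fully in log space.  Both are
JIT-compiled with numba when available; the pure-numpy fallbacks are
identical code paths, just slower.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def forward_loglik(log_b, gammas, pi0):
    """Scaled forward algorithm.

    log_b: (T, S) per-observation log emission densities.
    gammas: (T, S, S) transition matrix into each step; gammas[0] is unused.
    pi0: (S,) initial distribution.
    """
    T, S = log_b.shape
    ll = 0.0
    alpha = np.empty(S)
    m = log_b[0].max()
    for s in range(S):
        alpha[s] = pi0[s] * np.exp(log_b[0, s] - m)
    c = alpha.sum()
    if c <= 0.0:
        return -np.inf
    ll += np.log(c) + m
    alpha /= c
    tmp = np.empty(S)
    for t in range(1, T):
        m = log_b[t].max()
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[i] * gammas[t, i, j]
            tmp[j] = acc * np.exp(log_b[t, j] - m)
        c = tmp.sum()
        if c <= 0.0:
            return -np.inf
        ll += np.log(c) + m
        for j in range(S):
            alpha[j] = tmp[j] / c
    return ll


@njit(cache=True)
def forward_backward(log_b, gammas, pi0, zc):
    """Scaled forward-backward pass with transition-gradient accumulation.

    Returns (loglik, post, grad_beta) where post[t, s] is the posterior state
    probability and grad_beta is the gradient of the log likelihood with
    respect to the off-diagonal multinomial-logit parameters, laid out
    row-major (i, then j != i) with columns (intercept, one per covariate in
    zc).  Uses the identity d ll / d eta_ij = sum_t xi_t(i,j) -
    rowsum_xi_t(i) * Gamma_t(i,j).
    """
    T, S = log_b.shape
    C = zc.shape[1]
    alpha = np.empty((T, S))
    cs = np.empty(T)
    ms = np.empty(T)
    ll = 0.0
    m = log_b[0].max()
    ms[0] = m
    for s in range(S):
        alpha[0, s] = pi0[s] * np.exp(log_b[0, s] - m)
    c = alpha[0].sum()
    cs[0] = c
    ll += np.log(c) + m
    for s in range(S):
        alpha[0, s] /= c
    for t in range(1, T):
        m = log_b[t].max()
        ms[t] = m
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[t - 1, i] * gammas[t, i, j]
            alpha[t, j] = acc * np.exp(log_b[t, j] - m)
        c = alpha[t].sum()
        cs[t] = c
        ll += np.log(c) + m
        for j in range(S):
            alpha[t, j] /= c

    beta = np.ones(S)
    post = np.empty((T, S))
    for s in range(S):
        post[T - 1, s] = alpha[T - 1, s]
    grad_beta = np.zeros((S * (S - 1), 1 + C))
    new_beta = np.empty(S)
    for t in range(T - 1, 0, -1):
        # xi_t(i, j) = alpha_{t-1}(i) Gamma_t(i,j) b~_t(j) beta_t(j) / c_t;
        # gradient and backward recursion are accumulated in one sweep
        bshift = np.empty(S)
        for j in range(S):
            bshift[j] = np.exp(log_b[t, j] - ms[t]) * beta[j] / cs[t]
        k = 0
        for i in range(S):
            rowsum = 0.0
            for j in range(S):
                rowsum += alpha[t - 1, i] * gammas[t, i, j] * bshift[j]
            for j in range(S):
                if j != i:
                    xi = alpha[t - 1, i] * gammas[t, i, j] * bshift[j]
                    d = xi - rowsum * gammas[t, i, j]
                    grad_beta[k, 0] += d
                    for cc in range(C):
                        grad_beta[k, 1 + cc] += d * zc[t, cc]
                    k += 1
        for i in range(S):
            acc = 0.0
            for j in range(S):
                acc += gammas[t, i, j] * bshift[j]
            new_beta[i] = acc
        for i in range(S):
            beta[i] = new_beta[i]
            post[t - 1, i] = alpha[t - 1, i] * beta[i]
        tot = post[t - 1].sum()
        for i in range(S):
            post[t - 1, i] /= tot
    return ll, post, grad_beta


@njit(cache=True)
def viterbi_path(log_b, log_gammas, log_pi0):
    """Most probable state path; ties resolve to the lower state index."""
    T, S = log_b.shape
    delta = np.empty((T, S))
    back = np.zeros((T, S), dtype=np.int64)
    for s in range(S):
        delta[0, s] = log_pi0[s] + log_b[0, s]
    for t in range(1, T):
        for j in range(S):
            best = delta[t - 1, 0] + log_gammas[t, 0, j]
            arg = 0
            for i in range(1, S):
                v = delta[t - 1, i] + log_gammas[t, i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            delta[t, j] = best + log_b[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for s in range(1, S):
        if delta[T - 1, s] > best:
            best = delta[T - 1, s]
            arg = s
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
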