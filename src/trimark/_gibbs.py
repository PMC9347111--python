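"""Numba kernel for the admixture-model Gibbs sampler.

One chain updates, in turn: the latent population of origin of every
allele copy (multinomial conditional on ancestry and frequencies),
cluster allele frequencies (Beta conditional with a Beta(lambda, lambda)
prior), and per-sample ancestry proportions (Dirichlet conditional with
a symmetric Dirichlet(alpha) prior).  Retained sweeps are relabeled
against the first retained sweep by greedy column matching before the
posterior mean Q is accumulated; the data log-likelihood is recorded on
a thinned schedule for the model-evidence estimate.

The origin updates draw ~2 uniforms per call per sweep, so they use an
inline xorshift64* stream (seeded from the chain seed); the much rarer
Beta/Dirichlet updates use numpy's generator, seeded alongside.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(inline="always")
def _xs(state):
    """xorshift64* step: returns (uniform in [0,1), new state)."""
    state ^= state >> _U64(12)
    state ^= state << _U64(25)
    state ^= state >> _U64(27)
    val = state * _U64(2685821657736338717)
    return (val >> _U64(11)) * _INV53, state


@njit(cache=True)
def _greedy_perm(cost: np.ndarray) -> np.ndarray:
    """perm[k] = reference column assigned to current column k."""
    K = cost.shape[0]
    perm = np.full(K, -1, dtype=np.int64)
    used_row = np.zeros(K, dtype=np.bool_)
    used_col = np.zeros(K, dtype=np.bool_)
    for _ in range(K):
        best = -1.0
        bi = bj = 0
        for i in range(K):
            if used_row[i]:
                continue
            for j in range(K):
                if used_col[j]:
                    continue
                if cost[i, j] > best:
                    best = cost[i, j]
                    bi, bj = i, j
        perm[bi] = bj
        used_row[bi] = True
        used_col[bj] = True
    return perm


@njit(cache=True)
def run_chain(calls, K, alpha, lam, burn_in, sweeps, ll_thin, seed):
    """Run one Gibbs chain; returns (mean_Q, mean_P, lnL samples)."""
    np.random.seed(seed)
    st = _U64(seed) * _U64(6364136223846793005) + _U64(1442695040888963407)
    if st == _U64(0):
        st = _U64(88172645463325252)
    n, m = calls.shape

    # initial state
    p = np.empty((K, m))
    for k in range(K):
        for l in range(m):
            a = np.random.gamma(lam, 1.0)
            b = np.random.gamma(lam, 1.0)
            p[k, l] = a / (a + b)
    q = np.empty((n, K))
    for i in range(n):
        tot = 0.0
        for k in range(K):
            q[i, k] = np.random.gamma(alpha, 1.0) + 1e-12
            tot += q[i, k]
        for k in range(K):
            q[i, k] /= tot

    n_alt = np.zeros((K, m))
    n_ref = np.zeros((K, m))
    n_cop = np.zeros((n, K))
    w = np.empty(K)

    acc_q = np.zeros((n, K))
    acc_p = np.zeros((K, m))
    ref_q = np.zeros((n, K))
    perm = np.arange(K)
    have_ref = False
    n_ll = 0 if sweeps <= 0 else (sweeps + ll_thin - 1) // ll_thin
    lls = np.empty(n_ll)
    ll_i = 0

    for sweep in range(burn_in + sweeps):
        n_alt[:, :] = 0.0
        n_ref[:, :] = 0.0
        n_cop[:, :] = 0.0
        for i in range(n):
            for l in range(m):
                g = calls[i, l]
                if g < 0:
                    continue
                if g > 0:  # origins of the alternate-allele copies
                    tot = 0.0
                    for k in range(K):
                        w[k] = q[i, k] * p[k, l]
                        tot += w[k]
                    for _ in range(g):
                        u, st = _xs(st)
                        u *= tot
                        k = 0
                        acc = w[0]
                        while u > acc and k < K - 1:
                            k += 1
                            acc += w[k]
                        n_alt[k, l] += 1.0
                        n_cop[i, k] += 1.0
                if g < 2:  # origins of the reference-allele copies
                    tot = 0.0
                    for k in range(K):
                        w[k] = q[i, k] * (1.0 - p[k, l])
                        tot += w[k]
                    for _ in range(2 - g):
                        u, st = _xs(st)
                        u *= tot
                        k = 0
                        acc = w[0]
                        while u > acc and k < K - 1:
                            k += 1
                            acc += w[k]
                        n_ref[k, l] += 1.0
                        n_cop[i, k] += 1.0

        for k in range(K):
            for l in range(m):
                a = np.random.gamma(lam + n_alt[k, l], 1.0)
                b = np.random.gamma(lam + n_ref[k, l], 1.0)
                p[k, l] = a / (a + b)
        for i in range(n):
            tot = 0.0
            for k in range(K):
                q[i, k] = np.random.gamma(alpha + n_cop[i, k], 1.0) + 1e-12
                tot += q[i, k]
            for k in range(K):
                q[i, k] /= tot

        if sweep >= burn_in:
            if not have_ref:
                ref_q[:, :] = q
                have_ref = True
            else:
                cost = np.zeros((K, K))
                for i in range(n):
                    for k in range(K):
                        for j in range(K):
                            cost[k, j] += q[i, k] * ref_q[i, j]
                perm = _greedy_perm(cost)
            for i in range(n):
                for k in range(K):
                    acc_q[i, perm[k]] += q[i, k]
            for k in range(K):
                for l in range(m):
                    acc_p[perm[k], l] += p[k, l]

            r = sweep - burn_in
            if r % ll_thin == 0:
                ll = 0.0
                for i in range(n):
                    for l in range(m):
                        g = calls[i, l]
                        if g < 0:
                            continue
                        theta = 0.0
                        for k in range(K):
                            theta += q[i, k] * p[k, l]
                        if theta < 1e-12:
                            theta = 1e-12
                        if theta > 1.0 - 1e-12:
                            theta = 1.0 - 1e-12
                        if g == 0:
                            ll += 2.0 * np.log(1.0 - theta)
                        elif g == 2:
                            ll += 2.0 * np.log(theta)
                        else:
                            ll += np.log(2.0) + np.log(theta) + np.log(1.0 - theta)
                lls[ll_i] = ll
                ll_i += 1

    if sweeps > 0:
        acc_q /= sweeps
        acc_p /= sweeps
    return acc_q, acc_p, lls[:ll_i]
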