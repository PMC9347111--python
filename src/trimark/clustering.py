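"""Clustering back-ends shared by all three marker systems.

UPGMA trees on any distance matrix, genotype PCA, Bayesian admixture
clustering (a STRUCTURE-style Gibbs sampler) with Evanno delta-K model
selection, and threshold-based group assignment from ancestry
proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .data_io import DistanceMatrix, GenotypeMatrix, MISSING, Tree

__all__ = [
    "StructureRun",
    "EvannoTable",
    "GroupAssignment",
    "upgma",
    "pca_genotypes",
    "structure_gibbs",
    "evanno_delta_k",
    "assign_groups",
]


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dist: DistanceMatrix) -> Tree:
    """Classic UPGMA agglomeration.

    Size-weighted average linkage; node heights are half the merge
    distance, so cophenetic distances reproduce the merge distances and
    the tree is ultrametric.  Ties break deterministically on the
    smallest pair of cluster indices (by creation order).
    """
    n = dist.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    d = dist.values.astype(float).copy()
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    index_of = {i: i for i in range(n)}  # cluster id -> row in d
    children = np.empty((n - 1, 2), dtype=int)
    heights = np.empty(n - 1)
    # work on a growing matrix: rows are cluster ids in creation order
    work = np.full((2 * n - 1, 2 * n - 1), np.inf)
    work[:n, :n] = d
    np.fill_diagonal(work, np.inf)
    for step in range(n - 1):
        best = (np.inf, None, None)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                v = work[a, b]
                if v < best[0] - 1e-15:
                    best = (v, a, b)
        dmin, a, b = best
        new = n + step
        children[step] = (a, b)
        heights[step] = dmin / 2.0
        sa, sb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            v = (sa * work[a, c] + sb * work[b, c]) / (sa + sb)
            work[new, c] = work[c, new] = v
        sizes[new] = sa + sb
        active.remove(a)
        active.remove(b)
        active.append(new)
    return Tree(list(dist.sample_ids), children, heights)


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------

def pca_genotypes(g: GenotypeMatrix, n_components: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix.

    Missing calls are replaced by the site mean (twice the alternate
    frequency) and every site is centered on that mean; coordinates come
    from the singular value decomposition of the centered matrix.
    Returns ``(coordinates, explained_fractions)`` with components in
    decreasing explained-variance order; the fractions sum to 1 over all
    components.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = g.calls.astype(float)
    x[g.calls == MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mean, inds[1])
    x -= mean
    if not np.any(x):
        raise ValueError("all sites monomorphic: PCA undefined")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u * s
    var = s ** 2
    frac = var / var.sum()
    if n_components is not None:
        coords = coords[:, :n_components]
        frac = frac[:n_components]
    return coords, frac


# ---------------------------------------------------------------------------
# Bayesian admixture clustering
# ---------------------------------------------------------------------------

@dataclass
class StructureRun:
    """One admixture-model chain: posterior mean ancestry and evidence."""

    K: int
    replicate: int
    Q: np.ndarray            # n x K posterior mean ancestry proportions
    mean_freqs: np.ndarray   # K x m posterior mean cluster frequencies
    lnpd: float              # Pritchard evidence estimate mean - var/2
    ln_likelihoods: np.ndarray
    burn_in: int
    reps: int
    alpha: float
    seed: int

    def __post_init__(self):
        rows = self.Q.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        if not np.isfinite(self.lnpd):
            raise ValueError("non-finite evidence estimate")


def structure_gibbs(g: GenotypeMatrix, K: int, burn_in: int = 10_000,
                    reps: int = 100_000, chains: int = 5, alpha: float = 1.0,
                    lam: float = 1.0, seed: int = 0,
                    ll_thin: int = 5) -> list[StructureRun]:
    """Admixture-model Gibbs sampling at one K, several replicate chains.

    ``reps`` counts post-burn-in sweeps.  The evidence estimate per chain
    is mean(lnL) - var(lnL)/2 over the retained (thinned) likelihood
    samples.  Label switching is resolved within a chain against its
    first retained sweep and across replicates against replicate 0, both
    by greedy matching of ancestry columns.  Deterministic under
    ``seed``.
    """
    from ._gibbs import run_chain

    if K < 1:
        raise ValueError("K must be >= 1")
    if K > g.n_samples:
        raise ValueError("K larger than the number of samples")
    if burn_in < 0 or reps < 1 or chains < 1:
        raise ValueError("burn_in >= 0, reps >= 1, chains >= 1 required")
    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2 ** 31 - 1, size=chains)
    runs: list[StructureRun] = []
    for rep in range(chains):
        q, p, lls = run_chain(np.ascontiguousarray(g.calls), K, alpha, lam,
                              burn_in, reps, ll_thin, int(chain_seeds[rep]))
        q = q / q.sum(axis=1, keepdims=True)
        lnpd = float(lls.mean() - lls.var() / 2.0)
        runs.append(StructureRun(K=K, replicate=rep, Q=q, mean_freqs=p,
                                 lnpd=lnpd, ln_likelihoods=lls,
                                 burn_in=burn_in, reps=reps, alpha=alpha,
                                 seed=int(chain_seeds[rep])))
    _align_replicates(runs)
    return runs


def _align_replicates(runs: list[StructureRun]) -> None:
    """Relabel every replicate's clusters to best match replicate 0."""
    if len(runs) < 2:
        return
    ref = runs[0].Q
    K = runs[0].K
    for run in runs[1:]:
        if K <= 6:
            best, best_perm = -np.inf, None
            for perm in permutations(range(K)):
                score = (run.Q[:, list(perm)] * ref).sum()
                if score > best:
                    best, best_perm = score, perm
            perm = list(best_perm)
        else:
            cost = run.Q.T @ ref
            perm = _greedy_assign(cost)
        run.Q = run.Q[:, perm]
        run.mean_freqs = run.mean_freqs[perm, :]


def _greedy_assign(cost: np.ndarray) -> list[int]:
    K = cost.shape[0]
    out = [-1] * K
    used = set()
    for _ in range(K):
        i, j = np.unravel_index(
            np.argmax(np.where(np.isneginf(cost), -np.inf, cost)), cost.shape)
        out[j] = i
        cost = cost.copy()
        cost[i, :] = -np.inf
        cost[:, j] = -np.inf
    return out


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class EvannoTable:
    """Evanno second-order statistics of the evidence across K."""

    table: pd.DataFrame  # K, n_reps, mean_lnpd, sd_lnpd, lprime, lsecond_abs, delta_k
    best_k: int | None


def evanno_delta_k(runs: list[StructureRun]) -> EvannoTable:
    """Delta-K model selection over a sweep of K values.

    delta K(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) using the
    replicate mean evidence L(K); defined for interior K only.  The best
    K maximizes delta K (None when every second difference is zero).
    Degenerate replicates (zero SD at an interior K) are an error.
    """
    by_k: dict[int, list[float]] = {}
    for run in runs:
        by_k.setdefault(run.K, []).append(run.lnpd)
    ks = sorted(by_k)
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need at least 3 consecutive K values")
    if min(len(v) for v in by_k.values()) < 2:
        raise ValueError("need at least 2 replicates per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lprime = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            lsecond = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            if sd[k] == 0:
                raise ValueError(f"zero replicate SD at K={k}: delta K undefined")
            dk = lsecond / sd[k]
        else:
            lsecond, dk = np.nan, np.nan
        rows.append({"K": k, "n_reps": len(by_k[k]), "mean_lnpd": mean[k],
                     "sd_lnpd": sd[k], "lprime": lprime,
                     "lsecond_abs": lsecond, "delta_k": dk})
    df = pd.DataFrame(rows)
    interior = df.dropna(subset=["delta_k"])
    best = None
    if len(interior) and interior["delta_k"].max() > 0:
        best = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return EvannoTable(table=df, best_k=best)


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

@dataclass
class GroupAssignment:
    labels: list          # cluster index (int) or "admixed"
    threshold: float
    assigned_fraction: float


def assign_groups(Q: np.ndarray, threshold: float = 0.60) -> GroupAssignment:
    """Assign each sample to its majority cluster when the membership
    proportion reaches ``threshold``, else mark it admixed."""
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[1]
    if not 1.0 / K < threshold <= 1.0:
        warnings.warn(
            f"threshold {threshold} outside (1/K, 1]: assignment is all-or-nothing",
            stacklevel=2)
    top = Q.argmax(axis=1)
    labels = [int(k) if Q[i, k] >= threshold else "admixed"
              for i, k in enumerate(top)]
    frac = float(np.mean([lab != "admixed" for lab in labels]))
    return GroupAssignment(labels=labels, threshold=threshold,
                           assigned_fraction=frac)
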