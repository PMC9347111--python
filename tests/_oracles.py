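"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from the defining formulas
(loops, enumeration) without reference to the implementation under test.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def cv_brute(values) -> float:
    """Coefficient of variation, percent, by the direct formula."""
    x = list(map(float, values))
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    return 100.0 * var ** 0.5 / mean


def pearson_brute(x, y) -> float:
    """Pearson correlation via the direct sum formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def pic_brute(p) -> float:
    """Botstein PIC with the nested double loop written out."""
    p = list(map(float, p))
    k = len(p)
    out = 1.0
    for i in range(k):
        out -= p[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            out -= 2.0 * p[i] ** 2 * p[j] ** 2
    return out


def tajima_constants(n: int) -> dict:
    """The a/b/c/e constants of the D statistic for n sequences."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": c1 / a1, "e2": c2 / (a1 ** 2 + a2)}


def mantel_exact_p(v1: np.ndarray, v2: np.ndarray) -> float:
    """Exact one-tailed Mantel p by enumerating all n! permutations."""
    n = v1.shape[0]
    iu = np.triu_indices(n, 1)
    x = v1[iu]

    def corr(mat):
        y = mat[iu]
        return pearson_brute(x.tolist(), y.tolist())

    r_obs = corr(v2)
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        p = np.array(perm)
        r = corr(v2[np.ix_(p, p)])
        hits += r >= r_obs - 1e-12
        total += 1
    return hits / total


def wc_fst(calls: np.ndarray, labels: np.ndarray) -> float:
    """Weir & Cockerham (1984) theta over two or more populations.

    ``calls`` is samples x sites with 0/1/2 and np.nan for missing.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    r = len(groups)
    a_sum = b_sum = c_sum = 0.0
    for j in range(calls.shape[1]):
        col = calls[:, j]
        ns, ps, hs = [], [], []
        for gname in groups:
            x = col[(labels == gname) & ~np.isnan(col)]
            if len(x) < 2:
                break
            ns.append(len(x))
            ps.append(x.mean() / 2.0)
            hs.append((x == 1).mean())
        else:
            n = np.array(ns, float)
            p = np.array(ps)
            h = np.array(hs)
            nbar = n.mean()
            pbar = (n * p).sum() / (r * nbar)
            if pbar <= 0 or pbar >= 1:
                continue
            hbar = (n * h).sum() / (r * nbar)
            nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            a = nbar / nc * (s2 - 1.0 / (nbar - 1)
                             * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
            b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            a_sum += a
            b_sum += b
            c_sum += c
    return a_sum / (a_sum + b_sum + c_sum)
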