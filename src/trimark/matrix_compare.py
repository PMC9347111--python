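"""Mantel comparison of marker-derived distance matrices.

The Mantel statistic r is the Pearson correlation of the two matrices'
off-diagonal upper triangles; significance comes from simultaneous
row/column permutation of the second matrix (one-tailed upper, with the
(hits + 1) / (n_perm + 1) estimator).  Correlations are additionally
classified with the conventional four-band rubric: r >= 0.9 significant,
0.8 <= r < 0.9 moderate, 0.7 <= r < 0.8 weak, r < 0.7 none.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import DistanceMatrix

__all__ = ["MantelResult", "mantel", "classify_r", "pairwise_mantel"]


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_perm: int
    classification: str


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9999,
           seed: int | None = None) -> MantelResult:
    """Mantel test between two distance matrices over the same samples.

    Requires identical sample order and n >= 4.  A constant matrix has
    no defined correlation and is rejected.
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("distance matrices cover different sample sets")
    n = d1.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples")
    iu = np.triu_indices(n, 1)
    x = d1.values[iu]
    y = d2.values[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    xc = (x - x.mean()) / x.std()
    r_obs = float((xc * (y - y.mean())).mean() / y.std())

    rng = np.random.default_rng(seed)
    hits = 0
    v2 = d2.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = v2[np.ix_(perm, perm)][iu]
        r_p = float((xc * (yp - yp.mean())).mean() / yp.std())
        if r_p >= r_obs - 1e-12:  # count exact ties despite float noise
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, r_squared=r_obs ** 2, p_value=p,
                        n_perm=n_perm, classification=classify_r(r_obs))


def classify_r(r: float) -> str:
    """Four-band correlation label on r itself (not |r|)."""
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError("|r| must be <= 1")
    if r >= 0.9:
        return "significant correlation"
    if r >= 0.8:
        return "moderate correlation"
    if r >= 0.7:
        return "weak correlation"
    return "no correlation"


def pairwise_mantel(matrices: Mapping[str, DistanceMatrix],
                    n_perm: int = 9999,
                    seed: int | None = None) -> pd.DataFrame:
    """Mantel tests for every unordered pair of named matrices.

    Returns a tidy table (pair, r, R^2, p, classification), one row per
    pair in name order.
    """
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least 2 matrices")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(names, 2):
        res = mantel(matrices[a], matrices[b], n_perm=n_perm,
                     seed=int(rng.integers(0, 2 ** 31 - 1)))
        rows.append({"pair": f"{a} vs {b}", "first": a, "second": b,
                     "r": res.r, "r_squared": res.r_squared,
                     "p_value": res.p_value,
                     "classification": res.classification})
    return pd.DataFrame(rows)
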