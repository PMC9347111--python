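"""Phenotype diversity statistics for a germplasm panel.

Per-trait summaries (mean, sample SD, coefficient of variation), a
10-grade Shannon-Weiner diversity index, pairwise Pearson correlations
with two-tailed t-test significance, PCA of the trait correlation matrix,
z-scoring, Euclidean sample distances and between-groups (average
linkage) hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import spatial, stats

from .data_io import DistanceMatrix, PhenotypeTable, Tree

__all__ = [
    "TraitSummary",
    "GradeDistribution",
    "CorrResult",
    "PcaResult",
    "summarize_trait",
    "summarize_table",
    "shannon_grade_index",
    "correlation_matrix",
    "zscore",
    "pca_correlation",
    "euclidean_distances",
    "hcluster_between_groups",
]


@dataclass
class TraitSummary:
    mean: float
    sd: float            # sample SD, divisor n-1
    median: float
    mode: float          # most frequent value; smallest on ties
    range: float         # max - min
    cv: float            # 100 * sd / mean, percent
    shannon: float       # 10-grade Shannon-Weiner index, nats


@dataclass
class GradeDistribution:
    """Occupancy of the 10 diversity grades for one trait.

    Grade 1 collects values below mean - 2 SD, grade 10 values above
    mean + 2 SD; grades 2-9 split the +-2 SD band into eight half-open
    [lo, hi) intervals of width 0.5 SD.
    """

    boundaries: np.ndarray  # 9 interior cut points
    counts: np.ndarray      # 10 grade occupancies
    proportions: np.ndarray

    def __post_init__(self):
        assert self.counts.sum() > 0
        np.testing.assert_allclose(self.proportions.sum(), 1.0, atol=1e-9)


@dataclass
class CorrResult:
    traits: list[str]
    r: np.ndarray       # pairwise Pearson correlations
    p: np.ndarray       # two-sided p from t = r sqrt((n-2)/(1-r^2))
    stars: np.ndarray   # "", "*" (p<0.05), "**" (p<0.01)


@dataclass
class PcaResult:
    eigenvalues: np.ndarray      # descending
    contributions: np.ndarray    # percent of total
    cumulative: np.ndarray       # percent
    loadings: np.ndarray         # traits x components (unit eigenvectors)
    retained: np.ndarray         # indices with eigenvalue > 1
    traits: list[str]


def summarize_trait(values: np.ndarray) -> TraitSummary:
    """Basic moments plus the 10-grade Shannon index for one trait."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = float(x.std(ddof=1))
    uniq, counts = np.unique(x, return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # np.unique sorts: smallest modal value
    if sd == 0:
        shannon = 0.0
    else:
        _, shannon = shannon_grade_index(x)
    return TraitSummary(
        mean=mean, sd=sd, median=float(np.median(x)), mode=mode,
        range=float(x.max() - x.min()), cv=100.0 * sd / mean, shannon=shannon)


def summarize_table(table: PhenotypeTable):
    """Per-trait summaries for a whole table, as a tidy DataFrame."""
    import pandas as pd

    rows = {t: vars(summarize_trait(table.values[:, j]))
            for j, t in enumerate(table.traits)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "trait"
    return df


def shannon_grade_index(values: np.ndarray,
                        n_grades: int = 10) -> tuple[GradeDistribution, float]:
    """Shannon-Weiner index H' = -sum p_i ln p_i over diversity grades.

    The grading uses the trait's own mean and sample SD: grade 1 below
    mean - 2 SD, the top grade above mean + 2 SD, and 0.5 SD steps in
    between (left-closed, right-open, so a value exactly at mean - 2 SD
    falls in grade 2 and one at mean + 2 SD in grade 9).  A zero-SD trait
    occupies a single grade and returns H' = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if n_grades < 3:
        raise ValueError("need at least 3 grades")
    mean, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        counts = np.zeros(n_grades, dtype=int)
        counts[n_grades // 2] = x.size
        props = counts / x.size
        dist = GradeDistribution(np.full(n_grades - 1, mean), counts, props)
        return dist, 0.0
    # interior band is +-2 SD split into n_grades-2 equal steps
    edges = mean + sd * np.linspace(-2.0, 2.0, n_grades - 1)
    grade = np.digitize(x, edges)  # 0 .. n_grades-1
    counts = np.bincount(grade, minlength=n_grades)
    props = counts / x.size
    nz = props[props > 0]
    h = float(-(nz * np.log(nz)).sum())
    return GradeDistribution(edges, counts, props), h


def correlation_matrix(table: PhenotypeTable) -> CorrResult:
    """All pairwise Pearson correlations with two-tailed t-test p-values
    and the conventional 0.05 / 0.01 significance stars."""
    x = table.values
    n, t = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [table.traits[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance traits have undefined correlations: {bad}")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = rr * np.sqrt((n - 2) / np.maximum(1 - rr ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, 0.0)
    stars = np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))
    return CorrResult(list(table.traits), r, p, stars)


def zscore(table: PhenotypeTable) -> PhenotypeTable:
    """Standardize every trait to mean 0, sample SD 1."""
    sds = table.values.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [table.traits[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"cannot z-score constant traits: {bad}")
    z = (table.values - table.values.mean(axis=0)) / sds
    return PhenotypeTable(list(table.sample_ids), list(table.traits), z,
                          None if table.categories is None else list(table.categories))


def pca_correlation(table: PhenotypeTable) -> PcaResult:
    """PCA as an eigendecomposition of the trait correlation matrix.

    Eigenvalues sum to the trait count; contribution percentages to 100.
    Component signs are fixed so each component's largest-magnitude
    loading is positive.
    """
    if len(table.traits) < 2:
        raise ValueError("need at least 2 traits")
    sds = table.values.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant trait: correlation PCA undefined")
    corr = np.corrcoef(table.values, rowvar=False)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for k in range(v.shape[1]):
        j = np.argmax(np.abs(v[:, k]))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    contrib = 100.0 * w / w.sum()
    return PcaResult(
        eigenvalues=w, contributions=contrib, cumulative=np.cumsum(contrib),
        loadings=v, retained=np.flatnonzero(w > 1.0), traits=list(table.traits))


def euclidean_distances(table: PhenotypeTable) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample trait vectors.

    The pipeline z-scores the table first so every trait contributes on a
    common scale.
    """
    d = spatial.distance.squareform(spatial.distance.pdist(table.values))
    return DistanceMatrix(list(table.sample_ids), d)


def hcluster_between_groups(dist: DistanceMatrix) -> Tree:
    """Between-groups (average) linkage hierarchical clustering.

    Average linkage between merged groups is the UPGMA criterion, so this
    delegates to the shared UPGMA implementation; merge heights are
    monotone non-decreasing.
    """
    from .clustering import upgma

    return upgma(dist)
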