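"""Synthetic cohorts with the statistical structure of the study panel.

The real study genotyped 93 Xian (Indica) rice breeding lines with three
marker systems; the raw SSR and SNP matrices are not published, so this
module generates stand-ins with the documented structure:

* SNPs: two ancestral populations under the Balding-Nichols model with a
  target fixation index, Dirichlet admixture, a bounded ancestral
  minor-allele-frequency spectrum, block-wise shared ancestry to induce
  local LD, partial selfing (rice is a selfer; the study observed ~5%
  heterozygous calls), and random missingness.
* SSRs: 48-primer dominant band panels with 1-14 alleles per primer,
  scored as band presence the way silver-stained gels are read.
* Phenotypes: multivariate normal traits with the published per-trait
  means/SDs and correlation structure.

The packaged transcription of the study's printed 93 x 15 phenotype table
and of its 48-primer summary table are exposed as fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (BandMatrix, GenotypeMatrix, MISSING, PhenotypeTable,
                      PrimerInfo, ValidationError, read_phenotypes)

__all__ = [
    "PopulationSpec",
    "SsrPanelSpec",
    "PhenoSpec",
    "simulate_genotypes",
    "simulate_ssr",
    "simulate_phenotypes",
    "table1_fixture",
    "table5_fixture",
    "default_pheno_spec",
]


def _data_path(name: str):
    return resources.files("trimark.data").joinpath(name)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Parameters of the Balding-Nichols admixture generator.

    Defaults mirror the study panel: 93 lines, two subpopulations with a
    fixation index of 0.61, mostly unadmixed ancestry, ancestral allele
    frequencies on [0.05, 0.5], 12 chromosomes with ~5 kb marker spacing,
    30 kb ancestry blocks, and enough selfing to leave ~5% heterozygous
    calls.
    """

    n_samples: int = 93
    n_sites: int = 5000
    K: int = 2
    F: float = 0.61
    alpha: float = 0.05
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    selfing: float = 0.65
    block_r: float = 0.9
    block_length_bp: int = 30_000
    site_spacing_bp: int = 5_000
    n_chromosomes: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.F < 1:
            raise ValueError("F must be in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("maf_bounds must be inside (0, 1)")
        if not 0 <= self.selfing <= 1:
            raise ValueError("selfing must be in [0, 1]")
        if not 0 <= self.block_r < 1:
            raise ValueError("block_r must be in [0, 1)")


@dataclass
class SsrPanelSpec:
    """Parameters of the dominant SSR band generator."""

    n_primers: int = 48
    allele_count_range: tuple[int, int] = (1, 14)
    n_samples: int = 93
    missing_rate: float = 0.02
    group_concentration: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_count_range
        if lo < 1 or hi < lo:
            raise ValueError("allele counts must be >= 1 with lo <= hi")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class PhenoSpec:
    """Parameters of the multivariate-normal phenotype generator.

    ``means``/``sds``/``corr`` default to the published per-trait moments
    and correlation structure of the study panel.  ``kinds`` marks traits
    that are rounded to integers or clipped to [0, 100] after the draw.
    """

    traits: list[str]
    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray
    kinds: list[str] | None = None
    n_samples: int = 93
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        t = len(self.traits)
        if self.means.shape != (t,) or self.sds.shape != (t,):
            raise ValueError("means/sds must have one entry per trait")
        if np.any(self.sds <= 0):
            raise ValueError("trait SDs must be > 0")
        if self.corr.shape != (t, t):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.corr, self.corr.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")


def default_pheno_spec(n_samples: int = 93, seed: int = 0) -> PhenoSpec:
    """PhenoSpec with the published trait moments and correlations."""
    ref = pd.read_csv(_data_path("trait_reference.csv"))
    corr = np.loadtxt(_data_path("trait_correlations.csv"), delimiter=",")
    return PhenoSpec(
        traits=ref["trait"].tolist(),
        means=ref["mean"].to_numpy(),
        sds=ref["sd"].to_numpy(),
        corr=corr,
        kinds=ref["kind"].tolist(),
        n_samples=n_samples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# SNP genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(spec: PopulationSpec
                       ) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Draw a genotype matrix plus its true ancestry.

    Returns ``(genotypes, Q, labels)`` where ``Q`` is the per-sample true
    ancestry proportion matrix (n x K) and ``labels`` its argmax.

    Model: per site an ancestral frequency p ~ U(maf_bounds); population
    frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding-Nichols, so F is
    the expected fixation index); per sample Q ~ Dirichlet(alpha * 1_K);
    the two allele copies of each ancestry block draw their population of
    origin from Q (shared across the block's sites); with probability
    ``selfing`` a block's two copies are identical by descent.  Within a
    block each copy's alleles are drawn through a Gaussian copula with a
    shared latent factor (loading ``block_r``), so per-site marginals are
    exactly Bernoulli(p_origin) while within-block haplotypes show the
    strong local LD of a selfing population; missing entries are masked
    at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, K = spec.n_samples, spec.n_sites, spec.K

    chrom, pos = _site_map(spec)
    lo, hi = spec.maf_bounds
    p_anc = rng.uniform(lo, hi, size=m)
    a = p_anc * (1 - spec.F) / spec.F
    b = (1 - p_anc) * (1 - spec.F) / spec.F
    p_pop = rng.beta(a, b, size=(K, m))  # population x site frequencies

    Q = rng.dirichlet(np.full(K, spec.alpha), size=n)

    # ancestry blocks: sites on the same chromosome whose positions fall in
    # the same block_length_bp bin share their origin draws
    block_id = _block_ids(chrom, pos, spec.block_length_bp)
    n_blocks = block_id.max() + 1

    cum = np.cumsum(Q, axis=1)
    z1 = (rng.random((n, n_blocks))[:, :, None] > cum[:, None, :]).sum(-1)
    z2 = (rng.random((n, n_blocks))[:, :, None] > cum[:, None, :]).sum(-1)
    ibd = rng.random((n, n_blocks)) < spec.selfing

    from scipy.stats import norm

    p1 = p_pop[z1[:, block_id], np.arange(m)[None, :]]
    p2 = p_pop[z2[:, block_id], np.arange(m)[None, :]]
    # copula draw: allele = 1 iff sqrt(r) u_block + sqrt(1-r) e_site falls
    # below the origin frequency's normal quantile
    rho = np.sqrt(spec.block_r)
    tail = np.sqrt(1.0 - spec.block_r)
    u1 = rng.standard_normal((n, n_blocks))[:, block_id]
    u2 = rng.standard_normal((n, n_blocks))[:, block_id]
    copy1 = rho * u1 + tail * rng.standard_normal((n, m)) < norm.ppf(p1)
    copy2 = rho * u2 + tail * rng.standard_normal((n, m)) < norm.ppf(p2)
    copy2 = np.where(ibd[:, block_id], copy1, copy2)
    calls = (copy1.astype(np.int8) + copy2.astype(np.int8))

    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        calls[mask] = MISSING

    samples = [f"S{i + 1:03d}" for i in range(n)]
    g = GenotypeMatrix(samples, chrom, pos, calls)
    return g, Q, Q.argmax(axis=1)


def _site_map(spec: PopulationSpec) -> tuple[np.ndarray, np.ndarray]:
    m, C = spec.n_sites, spec.n_chromosomes
    per = np.full(C, m // C)
    per[: m % C] += 1
    chrom = np.concatenate([
        np.full(k, f"chr{c + 1}", dtype=object) for c, k in enumerate(per)])
    pos = np.concatenate([
        (np.arange(k) + 1) * spec.site_spacing_bp for k in per])
    return chrom, pos.astype(np.int64)


def _block_ids(chrom: np.ndarray, pos: np.ndarray, block_bp: int) -> np.ndarray:
    key = pd.factorize(pd.Series(chrom).astype(str) + ":" +
                       pd.Series(pos // max(block_bp, 1)).astype(str))[0]
    # renumber blocks in site order
    _, first = np.unique(key, return_index=True)
    rank = {key[i]: r for r, i in enumerate(np.sort(first))}
    return np.array([rank[k] for k in key])


# ---------------------------------------------------------------------------
# SSR bands
# ---------------------------------------------------------------------------

def simulate_ssr(spec: SsrPanelSpec,
                 assignments: Sequence[int] | None = None) -> BandMatrix:
    """Draw a dominant SSR band matrix.

    Each primer carries a codominant locus with 1-n alleles; every sample
    holds two allele copies and a band is scored present when either copy
    carries it (the information loss of dominant gel scoring).  When group
    ``assignments`` are given, allele frequencies are drawn independently
    per group so the grouping is recoverable from band profiles.  Code 9
    marks a sample missing for the whole primer.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    if assignments is not None:
        assignments = np.asarray(assignments)
        if assignments.shape != (n,):
            raise ValueError("assignments length must equal n_samples")
        groups = np.unique(assignments)
    lo, hi = spec.allele_count_range

    primers, band_labels, band_primer, cols = [], [], [], []
    for j in range(spec.n_primers):
        name = f"SSR{j + 1:02d}"
        primers.append(PrimerInfo(name=name,
                                  chromosome=str(j % 12 + 1),
                                  annealing_c=55.0))
        n_alleles = int(rng.integers(lo, hi + 1))
        if assignments is None:
            freqs = {None: rng.dirichlet(np.ones(n_alleles))}
            keys = np.full(n, None)
        else:
            freqs = {g: rng.dirichlet(
                np.full(n_alleles, spec.group_concentration)) for g in groups}
            keys = assignments
        copies = np.empty((n, 2), dtype=int)
        for g, f in freqs.items():
            sel = np.flatnonzero(keys == g) if g is not None else np.arange(n)
            copies[sel] = rng.choice(n_alleles, size=(len(sel), 2), p=f)
        present = np.zeros((n, n_alleles), dtype=np.int8)
        present[np.arange(n), copies[:, 0]] = 1
        present[np.arange(n), copies[:, 1]] = 1
        if spec.missing_rate > 0:
            miss = rng.random(n) < spec.missing_rate
            present[miss] = 9
        for k in range(n_alleles):
            band_labels.append(f"{name}_{k + 1}")
            band_primer.append(j)
        cols.append(present)

    scores = np.concatenate(cols, axis=1)
    samples = [f"S{i + 1:03d}" for i in range(n)]
    return BandMatrix(samples, primers, band_labels,
                      np.array(band_primer), scores)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def repair_correlation(corr: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to the nearest PSD
    correlation matrix (eigenvalue clipping + diagonal rescale)."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= 0:
        return corr
    w = np.clip(w, min_eig, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return 0.5 * (fixed + fixed.T)


def simulate_phenotypes(spec: PhenoSpec) -> PhenotypeTable:
    """Draw a phenotype table from a multivariate normal with the
    requested per-trait moments and correlation structure."""
    corr = repair_correlation(spec.corr)
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        raise ValidationError("correlation matrix not PSD after repair")
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(spec.traits)))
    z = rng.standard_normal((spec.n_samples, len(spec.traits)))
    x = spec.means + (z @ L.T) * spec.sds
    if spec.kinds is not None:
        for j, kind in enumerate(spec.kinds):
            if kind == "integer":
                x[:, j] = np.round(x[:, j])
            elif kind == "percent":
                x[:, j] = np.clip(x[:, j], 0.0, 100.0)
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    return PhenotypeTable(samples, list(spec.traits), x)


# ---------------------------------------------------------------------------
# packaged in-paper fixtures
# ---------------------------------------------------------------------------

def table1_fixture() -> PhenotypeTable:
    """The transcribed printed phenotype table: 93 lines x 15 traits with
    maintainer/restorer/special categories.

    The transcription reproduces every published per-trait mean and SD to
    printed precision.  The two identical rows the source prints (W1 and
    W298) are preserved verbatim.
    """
    with resources.as_file(_data_path("phenotypes_93.csv")) as p:
        return read_phenotypes(p)


def table5_fixture() -> pd.DataFrame:
    """The transcribed 48-primer SSR panel summary: primer name,
    chromosome, annealing temperature, primer sequences, total bands
    (TNB), polymorphic bands (NPB), PPB (%) and PIC as printed."""
    with resources.as_file(_data_path("ssr_panel_48.csv")) as p:
        return pd.read_csv(p)
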