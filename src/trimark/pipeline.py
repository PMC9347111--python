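"""End-to-end tri-marker pipeline.

One config drives, per available marker set: phenotype summaries ->
z-scored Euclidean distances -> tree; SSR band statistics -> band
distances -> tree plus Bayesian clustering; SNP filtering -> MAF /
heterozygosity / LD / haplotype blocks / Tajima's D -> IBS distances ->
PCA / UPGMA / Bayesian clustering -> Evanno best K -> AMOVA on the
best-K assignment -> gene flow; and finally Mantel tests between every
pair of marker distance matrices.  All randomness flows from named seeds
in the config; every threshold and seed is echoed into the report log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import clustering, matrix_compare, phenotype_stats, snp_popgen, ssr_stats
from .data_io import (BandMatrix, DistanceMatrix, GenotypeMatrix,
                      read_band_matrix, read_genotypes, read_phenotypes,
                      write_band_matrix, write_genotypes, write_newick,
                      write_phenotypes, write_report)
from .synthetic_data import (PopulationSpec, SsrPanelSpec, default_pheno_spec,
                             simulate_genotypes, simulate_phenotypes,
                             simulate_ssr)

__all__ = ["PipelineConfig", "run_pipeline", "demo_generate", "bands_to_genotypes"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    phenotypes: str | None = None
    bands: str | None = None
    genotypes: str | None = None
    genotype_format: str | None = None
    out_dir: str = "trimark_out"

    # SNP filters
    min_depth: int = 2
    max_missing: float = 0.3
    min_maf: float = 0.05

    # LD / blocks
    window_kb: float = 200.0
    ld_max_sites: int = 600         # cap on sites entering the O(m^2) LD scan

    # clustering
    band_metric: str = "simple-matching"
    kmin: int = 1
    kmax: int = 5
    chains: int = 5
    burn_in: int = 10_000
    reps: int = 100_000
    alpha: float = 1.0
    membership_threshold: float = 0.60
    structure_max_sites: int = 300  # evenly thinned marker subset for MCMC

    # permutation tests
    n_perm: int = 9999

    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def validate(self) -> None:
        if not (self.phenotypes or self.bands or self.genotypes):
            raise ValueError("config provides no marker inputs")
        if self.kmin < 1 or self.kmax < self.kmin:
            raise ValueError("need 1 <= kmin <= kmax")


def bands_to_genotypes(bands: BandMatrix) -> GenotypeMatrix:
    """Recode dominant bands as pseudo-biallelic loci for the admixture
    sampler: band presence becomes a homozygous alternate call (dominant
    scoring cannot see heterozygotes), code 9 becomes missing."""
    from .data_io import BAND_MISSING, MISSING

    calls = np.where(bands.scores == BAND_MISSING, MISSING,
                     2 * (bands.scores == 1)).astype(np.int8)
    chrom = np.array([bands.primers[p].name for p in bands.band_primer],
                     dtype=object)
    pos = np.empty(len(bands.band_labels), dtype=np.int64)
    counter: dict[str, int] = {}
    for i, c in enumerate(chrom):
        counter[c] = counter.get(c, 0) + 1
        pos[i] = counter[c] * 1000
    return GenotypeMatrix(list(bands.sample_ids), chrom, pos, calls)


def _thin_sites(g: GenotypeMatrix, max_sites: int) -> GenotypeMatrix:
    if max_sites is None or g.n_sites <= max_sites:
        return g
    idx = np.linspace(0, g.n_sites - 1, max_sites).round().astype(int)
    return g.take_sites(np.unique(idx))


def _structure_stage(g: GenotypeMatrix, cfg: PipelineConfig, seed: int) -> dict:
    sub = _thin_sites(g, cfg.structure_max_sites)
    all_runs = []
    for k in range(cfg.kmin, cfg.kmax + 1):
        all_runs.extend(clustering.structure_gibbs(
            sub, K=k, burn_in=cfg.burn_in, reps=cfg.reps, chains=cfg.chains,
            alpha=cfg.alpha, seed=seed + k))
    out = {
        "n_sites_used": sub.n_sites,
        "lnpd": [{"K": r.K, "replicate": r.replicate, "lnpd": r.lnpd}
                 for r in all_runs],
    }
    best_k = None
    if cfg.kmax - cfg.kmin >= 2 and cfg.chains >= 2:
        ev = clustering.evanno_delta_k(all_runs)
        out["evanno"] = ev.table.to_dict(orient="list")
        best_k = ev.best_k
    out["best_k"] = best_k
    if best_k is not None and best_k >= 2:
        runs_k = [r for r in all_runs if r.K == best_k]
        q = np.mean([r.Q for r in runs_k], axis=0)
        q = q / q.sum(axis=1, keepdims=True)
        assign = clustering.assign_groups(q, cfg.membership_threshold)
        out["Q"] = q
        out["assignment"] = {
            "labels": [str(x) for x in assign.labels],
            "threshold": assign.threshold,
            "assigned_fraction": assign.assigned_fraction,
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage the config has inputs for; write the
    consolidated JSON report plus Newick / Q-matrix side files.

    A stage failure is recorded in the report log and re-raised as a
    nonzero exit by the CLI after the partial report is written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": dataclasses.asdict(config)}
    log: dict = {"seeds": {"root": config.seed}, "failures": {}}
    distances: dict[str, DistanceMatrix] = {}

    if config.phenotypes:
        try:
            table = read_phenotypes(config.phenotypes)
            summary = phenotype_stats.summarize_table(table)
            corr = phenotype_stats.correlation_matrix(table)
            pca = phenotype_stats.pca_correlation(table)
            z = phenotype_stats.zscore(table)
            dist = phenotype_stats.euclidean_distances(z)
            tree = phenotype_stats.hcluster_between_groups(dist)
            write_newick(tree, out / "phenotypes.nwk")
            distances["phenotypes"] = dist
            iu = np.triu_indices(dist.n_samples, 1)
            results["phenotypes"] = {
                "n_samples": table.n_samples,
                "traits": summary.reset_index().to_dict(orient="list"),
                "mean_cv": float(summary["cv"].mean()),
                "mean_shannon": float(summary["shannon"].mean()),
                "correlations": corr.r,
                "pca": {
                    "eigenvalues": pca.eigenvalues,
                    "contributions": pca.contributions,
                    "cumulative": pca.cumulative,
                    "n_retained": int(len(pca.retained)),
                },
                "distance": {
                    "mean": float(dist.values[iu].mean()),
                    "max": float(dist.values[iu].max()),
                    "min": float(dist.values[iu].min()),
                },
            }
        except Exception as exc:  # noqa: BLE001 - recorded and re-raised by CLI
            log["failures"]["phenotypes"] = f"{type(exc).__name__}: {exc}"

    if config.bands:
        try:
            bands = read_band_matrix(config.bands)
            per_primer, panel = ssr_stats.band_summary(bands)
            dist = ssr_stats.band_distance(bands, config.band_metric)
            tree = clustering.upgma(dist)
            write_newick(tree, out / "ssr.nwk")
            distances["ssr"] = dist
            results["ssr"] = {
                "per_primer": per_primer.to_dict(orient="list"),
                "panel": panel,
                "metric": config.band_metric,
            }
            pseudo = bands_to_genotypes(bands)
            structure = _structure_stage(pseudo, config, config.seed + 100)
            if "Q" in structure:
                np.savetxt(out / "ssr_Q.tsv", structure["Q"], delimiter="\t")
            results["ssr"]["structure"] = {
                k: v for k, v in structure.items() if k != "Q"}
        except Exception as exc:  # noqa: BLE001
            log["failures"]["ssr"] = f"{type(exc).__name__}: {exc}"

    if config.genotypes:
        try:
            g = read_genotypes(config.genotypes, config.genotype_format)
            g = snp_popgen.filter_variants(g, config.min_depth,
                                           config.max_missing, config.min_maf)
            sites = snp_popgen.maf_spectrum(g)
            window = int(config.window_kb * 1000)
            g_ld = _thin_sites(g, config.ld_max_sites)
            ld = snp_popgen.ld_scan(g_ld, window)
            blocks = snp_popgen.haplotype_blocks(g_ld, window)
            div = snp_popgen.tajimas_d(g)
            dist = snp_popgen.ibs_distance(g)
            tree = clustering.upgma(dist)
            write_newick(tree, out / "snp.nwk")
            distances["snp"] = dist
            coords, frac = clustering.pca_genotypes(g)
            structure = _structure_stage(g, config, config.seed + 200)
            if "Q" in structure:
                np.savetxt(out / "snp_Q.tsv", structure["Q"], delimiter="\t")
            iu = np.triu_indices(dist.n_samples, 1)
            snp_block: dict = {
                "n_samples": g.n_samples,
                "n_sites": g.n_sites,
                "mean_maf": sites.mean_maf,
                "het_rate": snp_popgen.het_rate(g),
                "ld": {"n_pairs": int(len(ld)),
                       "mean_r2": float(ld["r2"].mean()) if len(ld) else None},
                "blocks": snp_popgen.block_summary(blocks),
                "tajimas_d": div.D,
                "pi": div.pi,
                "segregating_sites": div.S,
                "pca_cumulative_3": float(frac[:3].sum()),
                "ibs": {"mean": float(dist.values[iu].mean()),
                        "min": float(dist.values[iu].min()),
                        "max": float(dist.values[iu].max())},
                "structure": {k: v for k, v in structure.items() if k != "Q"},
            }
            if "assignment" in structure:
                labels = np.array(structure["assignment"]["labels"])
                keep = labels != "admixed"
                kept_labels = labels[keep]
                if (len(np.unique(kept_labels)) >= 2
                        and np.all(np.bincount(
                            np.unique(kept_labels, return_inverse=True)[1]) >= 2)):
                    sub = DistanceMatrix(
                        [s for s, k in zip(dist.sample_ids, keep) if k],
                        dist.values[np.ix_(keep, keep)])
                    am = snp_popgen.amova(sub, kept_labels, config.n_perm,
                                          seed=config.seed + 300,
                                          already_squared=True)
                    snp_block["amova"] = {
                        "pct_among": am.pct_among, "pct_within": am.pct_within,
                        "phi_st": am.phi_st, "p_value": am.p_value,
                        "nm": am.nm, "n_perm": am.n_perm,
                        "excluded_admixed": int((~keep).sum()),
                    }
            results["snp"] = snp_block
        except Exception as exc:  # noqa: BLE001
            log["failures"]["snp"] = f"{type(exc).__name__}: {exc}"

    if len(distances) >= 2:
        try:
            mt = matrix_compare.pairwise_mantel(distances, config.n_perm,
                                                seed=config.seed + 400)
            results["mantel"] = mt.drop(columns=["first", "second"]).to_dict(
                orient="list")
        except Exception as exc:  # noqa: BLE001
            log["failures"]["mantel"] = f"{type(exc).__name__}: {exc}"

    results["log"] = log
    write_report(results, out / "report.json")
    return results


def demo_generate(seed: int = 1, out_dir: str | Path = "trimark_demo",
                  n_sites: int = 5000) -> Path:
    """Write a self-contained synthetic cohort sized like the study panel
    (93 lines, 2 subpopulations, 48 SSR primers, ~5000 SNPs) plus a
    desk-scale pipeline config; returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, q, labels = simulate_genotypes(
        PopulationSpec(n_sites=n_sites, seed=seed))
    write_genotypes(g, out / "genotypes.vcf", format="vcf")
    bands = simulate_ssr(SsrPanelSpec(seed=seed + 1), assignments=labels)
    bands.sample_ids = list(g.sample_ids)
    write_band_matrix(bands, out / "bands.csv")
    table = simulate_phenotypes(default_pheno_spec(seed=seed + 2))
    table.sample_ids = list(g.sample_ids)
    write_phenotypes(table, out / "phenotypes.csv")
    np.savetxt(out / "true_Q.tsv", q, delimiter="\t")
    cfg = PipelineConfig(
        phenotypes=str(out / "phenotypes.csv"),
        bands=str(out / "bands.csv"),
        genotypes=str(out / "genotypes.vcf"),
        out_dir=str(out / "results"),
        kmax=4, chains=2, burn_in=2000, reps=5000,
        n_perm=999, ld_max_sites=400, structure_max_sites=300,
        seed=seed,
    )
    cfg_path = out / "config.yaml"
    cfg.to_yaml(cfg_path)
    return cfg_path
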