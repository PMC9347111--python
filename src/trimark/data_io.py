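"""Core data containers and file I/O for the tri-marker pipeline.

Three marker systems feed the analysis: a phenotype table (samples x named
quantitative traits), a dominant SSR band matrix (presence/absence codes
grouped by primer), and a diploid SNP genotype matrix (alternate-allele
counts with chromosome/position metadata).  Every container validates its
invariants on construction; readers and writers round-trip losslessly on
valid inputs.

Conventions
-----------
* SNP positions are 1-based, chromosome labels are opaque strings (VCF
  convention).  Unplaced markers may carry a reserved label such as ``"Un"``;
  windowed LD analyses skip them while diversity statistics keep them.
* Genotype calls are coded 0/1/2 alternate-allele counts with ``-1`` for
  missing.  SSR band code 9 marks a sample missing for the whole primer.
* Missing phenotype values are rejected outright; missing genotypes and
  band code 9 are carried as explicit missing states, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "PhenotypeTable",
    "PrimerInfo",
    "BandMatrix",
    "GenotypeMatrix",
    "DistanceMatrix",
    "Tree",
    "read_phenotypes",
    "write_phenotypes",
    "read_band_matrix",
    "write_band_matrix",
    "read_genotypes",
    "write_genotypes",
    "write_newick",
    "write_report",
]

MISSING = -1  # genotype missing code
BAND_MISSING = 9  # SSR "complete absence of band"

CATEGORIES = ("maintainer", "restorer", "special")


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


class ParseError(ValueError):
    """A file cannot be interpreted as the requested container."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Samples x traits matrix of quantitative phenotype observations."""

    sample_ids: list[str]
    traits: list[str]
    values: np.ndarray
    categories: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.traits = [str(t) for t in self.traits]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dup}")
        if self.values.shape != (len(self.sample_ids), len(self.traits)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.traits)})")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"trait {self.traits[j]!r}")
        if self.categories is not None:
            self.categories = [str(c) for c in self.categories]
            if len(self.categories) != len(self.sample_ids):
                raise ValidationError("categories length != sample count")
            bad = sorted(set(self.categories) - set(CATEGORIES))
            if bad:
                raise ValidationError(f"unknown categories: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def trait_values(self, trait: str) -> np.ndarray:
        return self.values[:, self.traits.index(trait)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.traits)
        if self.categories is not None:
            df.insert(0, "category", self.categories)
        df.index.name = "sample"
        return df


@dataclass(frozen=True)
class PrimerInfo:
    name: str
    chromosome: str = "."
    annealing_c: float | None = None


@dataclass
class BandMatrix:
    """Dominant SSR scores: 1 band present, 0 absent, 9 sample missing.

    Bands are grouped under the primer that amplified them; each
    polymorphic band stands for one allele of that primer's locus.
    """

    sample_ids: list[str]
    primers: list[PrimerInfo]
    band_labels: list[str]
    band_primer: np.ndarray  # band index -> primer index
    scores: np.ndarray       # samples x bands, codes {0, 1, 9}

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.band_primer = np.asarray(self.band_primer, dtype=int)
        self.scores = np.asarray(self.scores, dtype=np.int8)
        n, b = len(self.sample_ids), len(self.band_labels)
        if self.scores.shape != (n, b):
            raise ValidationError(f"score matrix shape {self.scores.shape} != ({n}, {b})")
        if self.band_primer.shape != (b,):
            raise ValidationError("band_primer must assign every band to one primer")
        bad = set(np.unique(self.scores)) - {0, 1, 9}
        if bad:
            raise ValidationError(f"band codes outside {{0,1,9}}: {sorted(bad)}")
        counts = np.bincount(self.band_primer, minlength=len(self.primers))
        if (counts == 0).any():
            empty = [self.primers[i].name for i in np.flatnonzero(counts == 0)]
            raise ValidationError(f"primers without bands: {empty}")
        if self.band_primer.size and (self.band_primer.min() < 0
                                      or self.band_primer.max() >= len(self.primers)):
            raise ValidationError("band_primer index out of range")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def primer_bands(self, primer: str | int) -> np.ndarray:
        """Band column indices belonging to one primer."""
        if isinstance(primer, str):
            names = [p.name for p in self.primers]
            try:
                primer = names.index(primer)
            except ValueError:
                raise KeyError(f"unknown primer {primer!r}") from None
        return np.flatnonzero(self.band_primer == primer)


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as alternate-allele counts.

    ``calls[i, j]`` is 0/1/2 for sample i at site j, ``-1`` if missing.
    Sites are ordered with strictly increasing positions per chromosome.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.pos)
        if self.chrom.shape != (m,):
            raise ValidationError("chrom/pos length mismatch")
        if self.calls.shape != (n, m):
            raise ValidationError(f"call matrix shape {self.calls.shape} != ({n}, {m})")
        bad = set(np.unique(self.calls)) - {-1, 0, 1, 2}
        if bad:
            raise ValidationError(f"calls outside {{0,1,2,missing}}: {sorted(bad)}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValidationError(f"positions not strictly increasing on {c}")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != (n, m):
                raise ValidationError("depth shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            calls=self.calls[:, idx],
            ref=None if self.ref is None else np.asarray(self.ref)[idx],
            alt=None if self.alt is None else np.asarray(self.alt)[idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite distances")
        if np.any(self.values < 0):
            raise ValidationError("negative distances")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValidationError("nonzero diagonal")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("asymmetric distance matrix")
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy's condensed order."""
        iu = np.triu_indices(self.n_samples, 1)
        return self.values[iu]


@dataclass
class Tree:
    """Rooted ultrametric-capable tree from agglomerative clustering.

    Stored scipy-linkage style: leaves are ids ``0..n-1``; merge ``k``
    creates node ``n + k`` joining ``children[k]`` at height ``heights[k]``
    (height = distance from the node to any descendant leaf for ultrametric
    trees).
    """

    leaf_names: list[str]
    children: np.ndarray  # (n-1, 2) node ids
    heights: np.ndarray   # (n-1,) node heights

    def __post_init__(self) -> None:
        self.leaf_names = [str(s) for s in self.leaf_names]
        self.children = np.asarray(self.children, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        n = len(self.leaf_names)
        if n < 2:
            raise ValidationError("tree needs at least 2 leaves")
        if self.children.shape != (n - 1, 2) or self.heights.shape != (n - 1,):
            raise ValidationError("malformed merge arrays")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.heights[node - n])

    def to_newick(self) -> str:
        """Newick string with branch lengths (heights differenced)."""
        n = self.n_leaves

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - self.node_height(node)
            if node < n:
                return f"{_newick_escape(self.leaf_names[node])}:{bl:.10g}"
            a, b = self.children[node - n]
            h = self.heights[node - n]
            return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

        a, b = self.children[-1]
        h = self.heights[-1]
        return f"({render(a, h)},{render(b, h)});"

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise leaf distances through the tree (2x merge height)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        d = np.zeros((n, n))
        for k in range(n - 1):
            a, b = self.children[k]
            for i in members[a]:
                for j in members[b]:
                    d[i, j] = d[j, i] = 2.0 * self.heights[k]
            members[n + k] = members.pop(a) + members.pop(b)
        return DistanceMatrix(list(self.leaf_names), d)


def _newick_escape(label: str) -> str:
    if any(c in label for c in "(),:; \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# phenotype I/O
# ---------------------------------------------------------------------------

def _delim_for(path: Path, dialect: str | None) -> str:
    if dialect:
        return {"csv": ",", "tsv": "\t", ",": ",", "\t": "\t"}.get(dialect, dialect)
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_phenotypes(path: str | Path, dialect: str | None = None) -> PhenotypeTable:
    """Read a delimited phenotype table (header row names the traits).

    The first column holds sample ids; an optional ``category`` column holds
    the maintainer/restorer/special label.  Any non-numeric trait cell is a
    :class:`ParseError` naming its row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delim_for(path, dialect), dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected sample id column plus traits")
    sample_col = df.columns[0]
    samples = df[sample_col].tolist()
    categories = None
    trait_cols = list(df.columns[1:])
    if trait_cols and trait_cols[0].lower() in {"category", "type"}:
        categories = df[trait_cols[0]].tolist()
        trait_cols = trait_cols[1:]
    values = np.empty((len(samples), len(trait_cols)))
    for j, col in enumerate(trait_cols):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            i = bad[0]
            raise ParseError(
                f"{path}: non-numeric value {df[col][i]!r} for sample "
                f"{samples[i]!r}, trait {col!r}")
        values[:, j] = parsed.to_numpy()
    return PhenotypeTable(samples, trait_cols, values, categories)


def write_phenotypes(table: PhenotypeTable, path: str | Path,
                     dialect: str | None = None) -> None:
    path = Path(path)
    table.to_dataframe().to_csv(path, sep=_delim_for(path, dialect))


# ---------------------------------------------------------------------------
# SSR band matrix I/O
# ---------------------------------------------------------------------------

def read_band_matrix(path: str | Path,
                     primer_map: Mapping[str, str] | None = None,
                     dialect: str | None = None) -> BandMatrix:
    """Read a dominant band score matrix (samples x bands, codes 1/0/9).

    Band columns are assigned to primers either through ``primer_map``
    (band label -> primer name) or, by default, by splitting the band label
    at its last underscore (``RM583_1`` belongs to ``RM583``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delim_for(path, dialect), index_col=0)
    scores = df.to_numpy()
    if not np.issubdtype(scores.dtype, np.number):
        raise ParseError(f"{path}: non-numeric band codes")
    bad = set(np.unique(scores)) - {0, 1, 9}
    if bad:
        raise ValidationError(f"{path}: band codes outside {{1,0,9}}: {sorted(bad)}")
    band_labels = [str(c) for c in df.columns]
    if primer_map is None:
        primer_names = [lbl.rsplit("_", 1)[0] for lbl in band_labels]
    else:
        missing = [lbl for lbl in band_labels if lbl not in primer_map]
        if missing:
            raise ParseError(f"{path}: bands without primer assignment: {missing[:5]}")
        primer_names = [primer_map[lbl] for lbl in band_labels]
    primers: list[PrimerInfo] = []
    order: dict[str, int] = {}
    band_primer = np.empty(len(band_labels), dtype=int)
    for i, name in enumerate(primer_names):
        if name not in order:
            order[name] = len(primers)
            primers.append(PrimerInfo(name=name))
        band_primer[i] = order[name]
    return BandMatrix([str(s) for s in df.index], primers, band_labels,
                      band_primer, scores.astype(np.int8))


def write_band_matrix(bands: BandMatrix, path: str | Path,
                      dialect: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(bands.scores, index=bands.sample_ids, columns=bands.band_labels)
    df.index.name = "sample"
    df.to_csv(path, sep=_delim_for(path, dialect))


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None,
                   skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read diploid genotypes from VCF or a site x sample matrix TSV.

    VCF GT fields map as 0/0 -> 0, 0|1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing
    (phased and unphased separators are equivalent).  Multiallelic records
    are skipped when ``skip_multiallelic`` is true, otherwise rejected.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "matrix-tsv"
    if format == "vcf":
        return _read_vcf(path, skip_multiallelic)
    if format == "matrix-tsv":
        return _read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, skip_multiallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF has no sample columns")
    chrom, pos, ref, alt, rows = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                continue
            raise ParseError(f"{path}: multiallelic record at {var.CHROM}:{var.POS}")
        gts = var.genotype.array()
        if gts.shape[1] - 1 != 2:  # last column is the phase flag
            raise ParseError(
                f"{path}: ploidy {gts.shape[1] - 1} != 2 at {var.CHROM}:{var.POS}")
        alleles = gts[:, :2]
        calls = np.where((alleles < 0).any(axis=1), MISSING,
                         alleles.clip(min=0).sum(axis=1))
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        rows.append(calls.astype(np.int8))
    if not rows:
        raise ParseError(f"{path}: no usable biallelic records")
    return GenotypeMatrix(samples, np.array(chrom, dtype=object),
                          np.array(pos), np.array(rows, dtype=np.int8).T,
                          ref=np.array(ref, dtype=object),
                          alt=np.array(alt, dtype=object))


def _read_matrix_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"chrom", "pos"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: matrix TSV needs 'chrom' and 'pos' columns")
    meta = [c for c in ("chrom", "pos", "ref", "alt") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns")
    calls = np.full((len(sample_cols), len(df)), MISSING, dtype=np.int8)
    for i, c in enumerate(sample_cols):
        col = df[c].to_numpy()
        ok = ~pd.isna(col) & (col != "NA") & (col != ".") & (col != "")
        vals = pd.to_numeric(pd.Series(col[ok]), errors="coerce")
        if vals.isna().any() or not set(vals.dropna().unique()) <= {0, 1, 2}:
            raise ParseError(f"{path}: sample column {c!r} has calls outside 0/1/2/NA")
        calls[i, np.flatnonzero(ok)] = vals.to_numpy(dtype=np.int8)
    return GenotypeMatrix(
        sample_cols, df["chrom"].to_numpy(dtype=object),
        df["pos"].astype(int).to_numpy(), calls,
        ref=df["ref"].to_numpy(dtype=object) if "ref" in df else None,
        alt=df["alt"].to_numpy(dtype=object) if "alt" in df else None)


def write_genotypes(g: GenotypeMatrix, path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "matrix-tsv"
    if format == "vcf":
        _write_vcf(g, path)
    elif format == "matrix-tsv":
        _write_matrix_tsv(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    ref = g.ref if g.ref is not None else np.full(g.n_sites, "A", dtype=object)
    alt = g.alt if g.alt is not None else np.full(g.n_sites, "T", dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j in range(g.n_sites):
            gts = "\t".join(code[int(v)] for v in g.calls[:, j])
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def _write_matrix_tsv(g: GenotypeMatrix, path: Path) -> None:
    data = {"chrom": g.chrom, "pos": g.pos}
    if g.ref is not None:
        data["ref"] = g.ref
    if g.alt is not None:
        data["alt"] = g.alt
    for i, s in enumerate(g.sample_ids):
        col = g.calls[i].astype(object)
        col[g.calls[i] == MISSING] = "NA"
        data[s] = col
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tree + report output
# ---------------------------------------------------------------------------

def write_newick(tree: Tree, path: str | Path) -> None:
    """Serialize a tree to a standard Newick file (re-parseable)."""
    if tree is None:
        raise ValidationError("no tree to write")
    Path(path).write_text(tree.to_newick() + "\n")


_KNOWN_STAGES = {
    "phenotypes", "ssr", "snp", "clustering", "structure", "amova",
    "mantel", "ld", "config", "log",
}


def write_report(results: Mapping[str, object], path: str | Path) -> None:
    """Write a machine-readable JSON report of completed stage outputs.

    ``results`` maps stage names (``phenotypes``, ``ssr``, ``snp``,
    ``structure``, ``amova``, ``mantel``, ...) to JSON-serializable
    summaries; unknown stage keys are rejected to catch typos.
    """
    unknown = set(results) - _KNOWN_STAGES
    if unknown:
        raise ValueError(f"unknown report stage keys: {sorted(unknown)}")
    Path(path).write_text(json.dumps(_jsonify(results), indent=2, sort_keys=True) + "\n")


def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if obj is None or isinstance(obj, (str, bool)):
        return obj
    raise TypeError(f"cannot serialize {type(obj).__name__} in report")
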