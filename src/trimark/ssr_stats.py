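"""Dominant SSR band statistics.

Each polymorphic band amplified by a primer is treated as one allele of
that primer's locus; band frequencies are normalized within the primer.
Per-primer outputs are total bands (TNB), polymorphic bands (NPB), the
percentage of polymorphic bands (PPB = 100 NPB / TNB) and the Botstein
polymorphism information content (PIC), classified as low (< 0.25),
moderate (0.25-0.5) or high (> 0.5).  Band-sharing distances feed the
clustering and Mantel stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import BAND_MISSING, BandMatrix, DistanceMatrix

__all__ = [
    "PrimerStats",
    "allele_frequencies",
    "pic",
    "pic_class",
    "ppb",
    "band_summary",
    "band_distance",
]


@dataclass
class PrimerStats:
    primer: str
    tnb: int
    npb: int
    ppb: float
    pic: float
    pic_class: str
    frequencies: np.ndarray


def _primer_scores(bands: BandMatrix, primer) -> np.ndarray:
    cols = bands.primer_bands(primer)
    scores = bands.scores[:, cols]
    scored = ~np.any(scores == BAND_MISSING, axis=1)  # code 9 = whole primer missing
    if not scored.any():
        raise ValueError("all samples missing for primer")
    return scores[scored]


def allele_frequencies(bands: BandMatrix, primer) -> np.ndarray:
    """Band ("allele") frequencies for one primer.

    Presence counts over scored samples, normalized to sum to 1 within
    the primer; samples with code 9 are excluded.
    """
    scores = _primer_scores(bands, primer)
    counts = (scores == 1).sum(axis=0).astype(float)
    total = counts.sum()
    if total == 0:
        # no band observed at all: uniform over the primer's bands
        return np.full(scores.shape[1], 1.0 / scores.shape[1])
    return counts / total


def pic(p: np.ndarray) -> float:
    """Botstein polymorphism information content.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2 for allele frequencies
    summing to 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must be non-negative and sum to 1")
    sq = p ** 2
    s2 = sq.sum()
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = s2 ** 2 - (sq ** 2).sum()
    return float(1.0 - s2 - cross)


def pic_class(value: float) -> str:
    if value < 0.25:
        return "low"
    if value <= 0.5:
        return "moderate"
    return "high"


def ppb(bands: BandMatrix, primer) -> float:
    """Percentage of polymorphic bands for one primer.

    A band is polymorphic iff it is present in at least one and absent in
    at least one scored sample.
    """
    scores = _primer_scores(bands, primer)
    present = (scores == 1).sum(axis=0)
    poly = (present > 0) & (present < scores.shape[0])
    return 100.0 * poly.sum() / scores.shape[1]


def band_summary(bands: BandMatrix) -> tuple[pd.DataFrame, dict]:
    """Per-primer TNB/NPB/PPB/PIC table plus panel-level means."""
    rows = []
    for i, primer in enumerate(bands.primers):
        freqs = allele_frequencies(bands, i)
        scores = _primer_scores(bands, i)
        present = (scores == 1).sum(axis=0)
        poly = (present > 0) & (present < scores.shape[0])
        value = pic(freqs)
        rows.append(PrimerStats(
            primer=primer.name, tnb=scores.shape[1], npb=int(poly.sum()),
            ppb=100.0 * poly.sum() / scores.shape[1], pic=value,
            pic_class=pic_class(value), frequencies=freqs))
    df = pd.DataFrame([{k: v for k, v in vars(r).items() if k != "frequencies"}
                       for r in rows])
    panel = {
        "n_primers": len(rows),
        "tnb_total": int(df["tnb"].sum()),
        "npb_total": int(df["npb"].sum()),
        "ppb_mean": float(df["ppb"].mean()),
        "pic_mean": float(df["pic"].mean()),
        "pic_min": float(df["pic"].min()),
        "pic_max": float(df["pic"].max()),
    }
    return df, panel


def band_distance(bands: BandMatrix, metric: str = "simple-matching") -> DistanceMatrix:
    """Pairwise band-profile dissimilarity with pairwise deletion.

    Bands where either sample carries code 9 are excluded for that pair.
    ``simple-matching``: mismatches / compared bands.  ``dice``:
    1 - 2a / (2a + b + c) on presence counts (a = shared presences,
    b/c = presences unique to either sample).
    """
    if metric not in {"simple-matching", "dice"}:
        raise ValueError(f"unknown metric {metric!r}")
    s = bands.scores
    n = bands.n_samples
    valid = s != BAND_MISSING
    pres = (s == 1) & valid
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid  # (n, B) comparable bands vs every sample
        comparable = both.sum(axis=1)
        if np.any(comparable == 0):
            j = int(np.flatnonzero(comparable == 0)[0])
            if j != i:
                raise ValueError(
                    f"samples {bands.sample_ids[i]!r} and {bands.sample_ids[j]!r} "
                    "share no scored bands")
        a = (pres[i] & pres & both).sum(axis=1)
        mism = ((pres[i] ^ pres) & both).sum(axis=1)
        if metric == "simple-matching":
            with np.errstate(invalid="ignore"):
                d[i] = mism / comparable
        else:
            denom = 2 * a + mism
            d[i] = np.where(denom > 0, 1.0 - 2 * a / np.maximum(denom, 1), 0.0)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(bands.sample_ids), d)
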