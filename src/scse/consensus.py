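"""Weighted consensus (typical) enhancer calling from a cell-type matrix.

Each single cell's peak profile is treated as an independent dataset.
Cells are weighted by their summed Tanimoto similarity to every other
cell (normalised over all ordered cell pairs, so weights sum to one),
and the consensus signal of a peak is the weight-combined fragment
count.  A peak is a typical enhancer when it passes all four QC
criteria:

i.   signal in at least one-third of the cells (``ceil(m/3)``);
ii.  no overlap (>= 1 bp) with promoter windows or exons;
iii. combined signal above the 95th percentile of a shuffled-peak null;
iv.  co-accessibility of at least 0.1 with a promoter-overlapping site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .intervals import FragmentIndex, overlaps_any
from .io import (FragmentRecord, GeneModel, GenomicInterval, PeakByCellMatrix,
                 promoter_window)

__all__ = ["tanimoto", "tanimoto_matrix", "cell_weights",
           "combined_peak_signal", "shuffle_null_threshold",
           "call_consensus_enhancers", "ConsensusEnhancer"]


@dataclass
class ConsensusEnhancer:
    interval: GenomicInterval
    combined_score: float
    support_fraction: float
    qc_flags: dict[str, bool] = field(default_factory=dict)
    max_promoter_coaccess: float = 0.0

    @property
    def is_typical(self) -> bool:
        return all(self.qc_flags.values())


def tanimoto(a, b) -> float:
    """Tanimoto coefficient A.B / (|A|^2 + |B|^2 - A.B) of two count vectors.

    Equals the Jaccard index when both vectors are binary.  Two all-zero
    vectors yield 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        warnings.warn("tanimoto of two all-zero vectors defined as 0")
        return 0.0
    return dot / denom


def tanimoto_matrix(matrix, max_cells: int | None = None,
                    seed: int | None = None) -> np.ndarray:
    """Pairwise Tanimoto coefficients among all cells (columns).

    Computed from the cells-by-cells Gram matrix of the sparse counts;
    the peaks-by-peaks product is never formed.  Above ``max_cells``,
    a seeded random subsample of cells is used (the returned matrix is
    then restricted to the subsample; see ``cell_weights`` note).
    """
    X = matrix.counts if isinstance(matrix, PeakByCellMatrix) else sp.csr_matrix(matrix)
    X = X.astype(float).tocsc()
    m = X.shape[1]
    if max_cells is not None and m > max_cells:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(m, size=max_cells, replace=False))
        X = X[:, keep]
        m = max_cells
    gram = np.asarray((X.T @ X).todense())
    sq = np.diag(gram).copy()
    denom = sq[:, None] + sq[None, :] - gram
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(denom > 0, gram / np.where(denom > 0, denom, 1.0), 0.0)
    return T


def cell_weights(T: np.ndarray) -> np.ndarray:
    """Per-cell weights from the Tanimoto matrix.

    ``w_t`` sums the off-diagonal similarities of cell ``t`` and is
    normalised by the sum over all ordered pairs ``i != k``, so the
    weights sum to exactly 1.  If every pair is dissimilar (zero
    denominator) uniform weights are returned with a warning.
    """
    T = np.asarray(T, dtype=float)
    m = T.shape[0]
    if m < 2:
        raise ValueError("need at least two cells")
    numer = T.sum(axis=1) - np.diag(T)
    denom = float(T.sum() - np.trace(T))
    if denom <= 0:
        warnings.warn("all cells mutually disjoint; using uniform weights")
        return np.full(m, 1.0 / m)
    return numer / denom


def combined_peak_signal(matrix, weights: np.ndarray) -> np.ndarray:
    """Weighted consensus signal per peak: sum_t count[peak, t] * w_t."""
    X = matrix.counts if isinstance(matrix, PeakByCellMatrix) else sp.csr_matrix(matrix)
    w = np.asarray(weights, dtype=float)
    if X.shape[1] != w.size:
        raise ValueError("weights not aligned to matrix cells")
    return np.asarray(X @ w).ravel()


def shuffle_null_threshold(
    fragments: Iterable[FragmentRecord] | FragmentIndex,
    peaks: Sequence[GenomicInterval],
    barcodes: Sequence[str],
    weights: np.ndarray,
    genome: dict[str, int],
    n_shuffles: int = 20,
    percentile: float = 95.0,
    seed: int | None = None,
) -> float:
    """Null threshold for criterion iii from randomly relocated peaks.

    Each replicate relocates every peak uniformly within its own
    chromosome (width preserved, overlaps permitted), recounts fragments
    per cell at the new positions, and recomputes the weighted combined
    signal.  The threshold is the given percentile of the pooled null
    scores over all replicates and peaks.
    """
    index = (fragments if isinstance(fragments, FragmentIndex)
             else FragmentIndex(fragments, barcodes))
    if index.n_fragments == 0:
        return 0.0
    # the index may cover more cells than this sub-matrix: project columns
    sel = None
    if list(index.barcodes) != list(barcodes):
        col_of = {b: i for i, b in enumerate(index.barcodes)}
        sel = np.array([col_of[b] for b in barcodes if b in col_of])
        if sel.size != len(barcodes):
            raise ValueError("fragment index missing matrix barcodes")
    for p in peaks:
        if p.chrom not in genome:
            raise ValueError(f"genome sizes missing chromosome {p.chrom!r}")
        if genome[p.chrom] < len(p):
            raise ValueError(f"chromosome {p.chrom} shorter than peak {p}")
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    null_scores = np.empty(n_shuffles * len(peaks))
    pos = 0
    for _ in range(n_shuffles):
        for p in peaks:
            width = len(p)
            start = int(rng.integers(0, genome[p.chrom] - width + 1))
            per_cell = index.count_in_region(p.chrom, start, start + width,
                                             per_cell=True)
            if sel is not None:
                per_cell = per_cell[sel]
            null_scores[pos] = float(per_cell @ w)
            pos += 1
    return float(np.percentile(null_scores, percentile))


def call_consensus_enhancers(
    matrix: PeakByCellMatrix,
    weights: np.ndarray,
    gene_models: Sequence[GeneModel],
    null_threshold: float | None,
    coaccess_links,
    support_fraction: float = 1.0 / 3.0,
    coaccess_cutoff: float = 0.1,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 100,
) -> list[ConsensusEnhancer]:
    """Score every peak and flag the four QC criteria.

    ``coaccess_links`` is a sequence of co-accessible pairs (site
    intervals + score) over this matrix's peak set, as produced by
    :func:`scse.coaccess.coaccessibility_scores`.  ``null_threshold``
    may be ``None`` when no fragment file is available; criterion iii is
    then skipped and flagged as passed with a warning.
    """
    m = matrix.n_cells
    scores = combined_peak_signal(matrix, weights)
    support = matrix.cells_per_peak()
    min_support = math.ceil(support_fraction * m)

    promoters = [promoter_window(g, promoter_upstream, promoter_downstream)
                 for g in gene_models]
    exons = [ex for g in gene_models for ex in g.exons]
    forbidden = overlaps_any(matrix.peaks, promoters + exons)
    promoter_peak = overlaps_any(matrix.peaks, promoters)

    # max co-accessibility to any promoter-overlapping site, per peak
    peak_index = {(p.chrom, p.start, p.end): i for i, p in enumerate(matrix.peaks)}
    max_coaccess = np.zeros(matrix.n_peaks)
    for pair in coaccess_links:
        ia = peak_index.get((pair.site_a.chrom, pair.site_a.start, pair.site_a.end))
        ib = peak_index.get((pair.site_b.chrom, pair.site_b.start, pair.site_b.end))
        if ia is None or ib is None:
            continue
        if promoter_peak[ib]:
            max_coaccess[ia] = max(max_coaccess[ia], pair.score)
        if promoter_peak[ia]:
            max_coaccess[ib] = max(max_coaccess[ib], pair.score)

    if null_threshold is None:
        warnings.warn("no fragment-based null available; criterion iii skipped")

    out: list[ConsensusEnhancer] = []
    for i, peak in enumerate(matrix.peaks):
        flags = {
            "support": bool(support[i] >= min_support),
            "annotation": bool(not forbidden[i]),
            "shuffle_null": (True if null_threshold is None
                             else bool(scores[i] > null_threshold)),
            "coaccessibility": bool(max_coaccess[i] >= coaccess_cutoff),
        }
        out.append(ConsensusEnhancer(peak, float(scores[i]),
                                     float(support[i]) / m, flags,
                                     float(max_coaccess[i])))
    return out
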