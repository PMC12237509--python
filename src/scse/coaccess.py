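"""Co-accessibility scoring and enhancer-promoter linking.

The procedure follows the standard scATAC co-accessibility recipe:
TF-IDF transform of the count matrix, LSI embedding (truncated SVD with
the depth-correlated first component dropped), aggregation of similar
cells into metacells, and a distance-penalised graphical lasso on the
metacell covariance within overlapping genomic windows.  The score of a
site pair is the negated scaled inverse-covariance entry (the partial
correlation); links to promoters at score >= 0.1 define
enhancer-promoter interactions.

The graphical lasso here supports a full penalty matrix (off-diagonal
penalty growing linearly with genomic distance, infinite beyond the
distance bound), which scalar-penalty library implementations do not;
it is a block coordinate-descent solver in the usual W/beta
parametrisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .io import GenomicInterval, PeakByCellMatrix

__all__ = ["tfidf_transform", "lsi_embed", "umap_embed",
           "aggregate_metacells", "coaccessibility_scores",
           "link_enhancer_promoter", "graphical_lasso_penalty",
           "EmbeddingCoords", "MetacellMatrix", "CoAccessiblePair",
           "EnhancerPromoterLink"]


@dataclass
class EmbeddingCoords:
    """Per-cell coordinates; ``retained`` drops the depth-correlated
    first component (components 2..n_components are used downstream)."""

    coords: np.ndarray
    n_components: int
    singular_values: np.ndarray | None = None

    @property
    def retained(self) -> np.ndarray:
        return self.coords[:, 1:]


@dataclass
class MetacellMatrix:
    counts: np.ndarray  # peaks x metacells
    membership: list[np.ndarray]

    @property
    def n_metacells(self) -> int:
        return self.counts.shape[1]


@dataclass
class CoAccessiblePair:
    site_a: GenomicInterval
    site_b: GenomicInterval
    score: float
    genomic_distance: float


@dataclass
class EnhancerPromoterLink:
    enhancer: GenomicInterval
    promoter_site: GenomicInterval
    gene: str
    score: float


def tfidf_transform(matrix) -> sp.csr_matrix:
    """TF-IDF transform: ln(1 + (count / cell_total) * (m / n_cells_with_peak) * 1e4)."""
    X = matrix.counts if isinstance(matrix, PeakByCellMatrix) else sp.csr_matrix(matrix)
    X = X.astype(float).tocsc()
    m = X.shape[1]
    cell_total = np.asarray(X.sum(axis=0)).ravel()
    if (cell_total == 0).any():
        raise ValueError("all-zero cells present; run preprocessing first")
    n_with_peak = np.asarray((X > 0).sum(axis=1)).ravel()
    idf = np.zeros_like(n_with_peak, dtype=float)
    nz = n_with_peak > 0
    idf[nz] = m / n_with_peak[nz]
    out = X.tocoo()
    vals = np.log1p((out.data / cell_total[out.col]) * idf[out.row] * 1e4)
    return sp.csr_matrix((vals, (out.row, out.col)), shape=X.shape)


def lsi_embed(tfidf: sp.spmatrix, n_components: int = 50,
              seed: int | None = None) -> EmbeddingCoords:
    """LSI: truncated SVD of the TF-IDF matrix, embedding the cells.

    Components are ordered by singular value; the caller's downstream
    steps use ``retained`` (components 2 onward).  Signs are fixed so
    the largest-magnitude coordinate of each component is positive,
    making the output reproducible across solver runs.
    """
    from sklearn.decomposition import TruncatedSVD

    X = sp.csr_matrix(tfidf).T  # cells x peaks
    limit = min(X.shape) - 1
    if n_components > limit:
        warnings.warn(f"only {limit} components available; requested "
                      f"{n_components}")
        n_components = limit
    svd = TruncatedSVD(n_components=n_components, algorithm="arpack",
                       random_state=seed)
    coords = svd.fit_transform(X)
    flip = np.sign(coords[np.argmax(np.abs(coords), axis=0),
                          np.arange(coords.shape[1])])
    flip[flip == 0] = 1.0
    coords = coords * flip
    return EmbeddingCoords(coords, n_components, svd.singular_values_)


def umap_embed(coords: EmbeddingCoords | np.ndarray, seed: int | None = None,
               method: str = "umap") -> np.ndarray:
    """2-D embedding of LSI coordinates for visualisation.

    ``method="umap"`` runs UMAP with a fixed seed; ``method="lsi"`` is a
    documented deterministic fallback returning the first two retained
    LSI components unchanged.
    """
    X = coords.retained if isinstance(coords, EmbeddingCoords) else np.asarray(coords)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 cells to embed")
    if method == "lsi":
        return X[:, :2].copy()
    if method != "umap":
        raise ValueError(f"unknown embedding method {method!r}")
    import umap

    reducer = umap.UMAP(n_components=2, random_state=seed)
    return reducer.fit_transform(X)


def aggregate_metacells(matrix, coords, k: int = 50, max_overlap: float = 0.8,
                        seed: int | None = None) -> MetacellMatrix:
    """Sum counts over k-nearest-neighbour groups of cells.

    Candidate seed cells are visited in seeded random order; a candidate
    metacell (the seed's k nearest neighbours in the embedding, itself
    included) is accepted unless it shares more than ``max_overlap * k``
    members with an already accepted one.
    """
    from sklearn.neighbors import NearestNeighbors

    X = matrix.counts if isinstance(matrix, PeakByCellMatrix) else sp.csr_matrix(matrix)
    C = coords.retained if isinstance(coords, EmbeddingCoords) else np.asarray(coords)
    m = X.shape[1]
    if m < k:
        warnings.warn(f"{m} cells < k={k}; returning a single metacell")
        members = [np.arange(m)]
    else:
        nn = NearestNeighbors(n_neighbors=k).fit(C)
        _, idx = nn.kneighbors(C)
        rng = np.random.default_rng(seed)
        order = rng.permutation(m)
        members = []
        accepted_sets: list[set] = []
        limit = max_overlap * k
        for seed_cell in order:
            cand = set(idx[seed_cell])
            if any(len(cand & acc) > limit for acc in accepted_sets):
                continue
            accepted_sets.append(cand)
            members.append(np.sort(idx[seed_cell]))
    counts = np.column_stack(
        [np.asarray(X[:, mem].sum(axis=1)).ravel() for mem in members])
    return MetacellMatrix(counts.astype(float), members)


def _soft(x: float, t: float) -> float:
    if t == np.inf:
        return 0.0
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def graphical_lasso_penalty(S: np.ndarray, rho: np.ndarray,
                            max_iter: int = 200, tol: float = 1e-5
                            ) -> np.ndarray:
    """Sparse inverse covariance with an element-wise penalty matrix.

    Block coordinate descent over columns; each column subproblem is an
    L1-penalised regression solved by coordinate descent.  ``rho`` may
    contain ``inf`` to force entries to zero.  Returns the precision
    matrix Theta; raises ``FloatingPointError`` on non-convergence.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if p == 1:
        return np.array([[1.0 / S[0, 0]]])
    W = S.copy()
    W[np.diag_indices_from(W)] += 1e-4
    B = np.zeros((p, p))  # column j holds beta for block j
    idx_all = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    off = ~np.eye(p, dtype=bool)
    for _ in range(max_iter):
        W_old = W[off].copy()
        for j in range(p):
            idx = idx_all[j]
            W11 = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            r12 = rho[idx, j]
            beta = B[idx, j].copy()
            for _inner in range(200):
                delta = 0.0
                for a in range(p - 1):
                    old = beta[a]
                    resid = s12[a] - W11[a] @ beta + W11[a, a] * old
                    new = _soft(resid, r12[a]) / W11[a, a]
                    if new != old:
                        beta[a] = new
                        delta = max(delta, abs(new - old))
                if delta < tol * 0.1:
                    break
            B[idx, j] = beta
            w12 = W11 @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        change = np.abs(W[off] - W_old).mean() if p > 1 else 0.0
        if change < tol:
            break
    else:
        raise FloatingPointError("graphical lasso did not converge")
    Theta = np.zeros((p, p))
    for j in range(p):
        idx = idx_all[j]
        beta = B[idx, j]
        denom = W[j, j] - W[idx, j] @ beta
        Theta[j, j] = 1.0 / denom
        Theta[idx, j] = -beta * Theta[j, j]
    return 0.5 * (Theta + Theta.T)


def coaccessibility_scores(metacells: MetacellMatrix,
                           peaks: Sequence[GenomicInterval],
                           max_dist: int = 500_000,
                           penalty_scale: float = 1.0,
                           seed: int | None = None
                           ) -> list[CoAccessiblePair]:
    """Distance-penalised partial correlations between nearby sites.

    The genome is tiled into windows of width ``2 * max_dist`` stepped by
    ``max_dist``; within each window the metacell counts are
    depth-normalised and unit-variance scaled, and the graphical lasso is
    solved with off-diagonal penalty ``penalty_scale * d / max_dist``
    (infinite beyond ``max_dist``).  Score(i, j) =
    -Theta_ij / sqrt(Theta_ii * Theta_jj).  A pair seen in several
    windows keeps the score from the window whose centre is closest to
    the pair midpoint.
    """
    if metacells.n_metacells < 5:
        raise ValueError("need at least 5 metacells")
    counts = metacells.counts
    depth = counts.sum(axis=0)
    depth[depth == 0] = 1.0
    norm = counts / depth
    mean = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, keepdims=True)
    usable = sd.ravel() > 0
    Z = np.zeros_like(norm)
    Z[usable] = (norm[usable] - mean[usable]) / sd[usable]

    mids = np.array([p.midpoint for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    best: dict[tuple[int, int], tuple[float, float]] = {}  # pair -> (centre gap, score)
    n_skipped = 0
    for chrom in sorted(set(chroms)):
        on_chrom = np.flatnonzero((chroms == chrom) & usable)
        if len(on_chrom) < 2:
            continue
        lo = mids[on_chrom].min()
        hi = mids[on_chrom].max()
        w0 = int(max(0, lo - max_dist) // max_dist)
        w1 = int(hi // max_dist) + 1
        for w in range(w0, w1):
            wstart = w * max_dist
            centre = wstart + max_dist
            inside = on_chrom[(mids[on_chrom] >= wstart)
                              & (mids[on_chrom] < wstart + 2 * max_dist)]
            if len(inside) < 2:
                continue
            Zw = Z[inside]
            S = (Zw @ Zw.T) / Zw.shape[1]
            d = np.abs(mids[inside][:, None] - mids[inside][None, :])
            rho = penalty_scale * d / max_dist
            rho[d > max_dist] = np.inf
            np.fill_diagonal(rho, 0.0)
            try:
                Theta = graphical_lasso_penalty(S, rho)
            except FloatingPointError:
                warnings.warn(f"graphical lasso failed in window "
                              f"{chrom}:{wstart}; window skipped")
                n_skipped += 1
                continue
            diag = np.sqrt(np.diag(Theta))
            for a in range(len(inside)):
                for b in range(a + 1, len(inside)):
                    if d[a, b] > max_dist or Theta[a, b] == 0.0:
                        continue
                    i, j = int(inside[a]), int(inside[b])
                    score = float(np.clip(-Theta[a, b] / (diag[a] * diag[b]),
                                          -1.0, 1.0))
                    pair_mid = 0.5 * (mids[i] + mids[j])
                    gap = abs(centre - pair_mid)
                    prev = best.get((i, j))
                    if prev is None or gap < prev[0]:
                        best[(i, j)] = (gap, score)
    pairs = []
    for (i, j), (_, score) in sorted(best.items()):
        a, b = peaks[i], peaks[j]
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            a, b = b, a
        pairs.append(CoAccessiblePair(a, b, score, abs(mids[i] - mids[j])))
    return pairs


def link_enhancer_promoter(pairs: Sequence[CoAccessiblePair],
                           promoters: Sequence[GenomicInterval],
                           cutoff: float = 0.1) -> list[EnhancerPromoterLink]:
    """Enhancer-promoter links: exactly one pair side in a promoter
    window, score >= cutoff.  The gene is read from the promoter window's
    ``name``; a side overlapping several promoters links to each gene."""
    links: list[EnhancerPromoterLink] = []
    for pair in pairs:
        if pair.score < cutoff:
            continue
        genes_a = [p for p in promoters if pair.site_a.overlaps(p)]
        genes_b = [p for p in promoters if pair.site_b.overlaps(p)]
        if bool(genes_a) == bool(genes_b):  # both or neither in promoters
            continue
        enh, prom_site, proms = ((pair.site_b, pair.site_a, genes_a)
                                 if genes_a else
                                 (pair.site_a, pair.site_b, genes_b))
        for prom in proms:
            links.append(EnhancerPromoterLink(enh, prom_site, prom.name,
                                              pair.score))
    return links
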