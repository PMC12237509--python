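import numpy as np
import pytest
import scipy.sparse as sp

from scse.coaccess import (CoAccessiblePair, aggregate_metacells,
                           coaccessibility_scores, graphical_lasso_penalty,
                           link_enhancer_promoter, lsi_embed, tfidf_transform,
                           umap_embed)
from scse.io import GenomicInterval


class TestTfidf:
    def test_hand_value_peak_in_all_cells(self):
        X = sp.csr_matrix(np.array([[1, 1], [1, 3]]))  # cell totals 2, 4
        tf = tfidf_transform(X)
        assert tf[0, 0] == pytest.approx(np.log(1 + 0.5 * 1 * 1e4))

    def test_zero_entries_stay_zero(self):
        X = sp.csr_matrix(np.array([[0, 2], [1, 1]]))
        tf = tfidf_transform(X)
        assert tf[0, 0] == 0.0

    def test_depth_invariance_of_tf(self, rng):
        X = rng.integers(0, 5, size=(12, 4)) + 1
        tf1 = tfidf_transform(sp.csr_matrix(X))
        X2 = X.copy()
        X2[:, 0] *= 2  # doubling a cell's counts leaves its TF unchanged
        tf2 = tfidf_transform(sp.csr_matrix(X2))
        assert np.allclose(tf1[:, 0].todense(), tf2[:, 0].todense())

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            tfidf_transform(sp.csr_matrix(np.array([[1, 0], [2, 0]])))


class TestLsi:
    def test_matches_dense_svd_oracle(self, rng):
        X = rng.random((30, 20))  # peaks x cells
        emb = lsi_embed(sp.csr_matrix(X), n_components=5, seed=0)
        U, s, Vt = np.linalg.svd(X.T, full_matrices=False)
        oracle = U[:, :5] * s[:5]
        for k in range(5):  # sign-free comparison per component
            dot = abs(oracle[:, k] @ emb.coords[:, k])
            norm = np.linalg.norm(oracle[:, k]) * np.linalg.norm(emb.coords[:, k])
            assert dot == pytest.approx(norm, abs=1e-8)

    def test_rank_one_matrix_later_components_vanish(self):
        X = np.outer(np.arange(1, 11), np.arange(1, 7)).astype(float)
        emb = lsi_embed(sp.csr_matrix(X), n_components=3, seed=0)
        assert np.abs(emb.retained).max() < 1e-6

    def test_requesting_too_many_components_warns(self, rng):
        X = sp.csr_matrix(rng.random((6, 5)))
        with pytest.warns(UserWarning, match="components"):
            emb = lsi_embed(X, n_components=50, seed=0)
        assert emb.coords.shape[1] == 4

    def test_reconstruction_error_non_increasing(self, rng):
        X = rng.random((25, 15))
        errs = []
        for k in (2, 5, 10):
            emb = lsi_embed(sp.csr_matrix(X), n_components=k, seed=0)
            # energy captured grows with k
            errs.append((emb.singular_values ** 2).sum())
        assert errs[0] <= errs[1] <= errs[2]


class TestUmap:
    def test_lsi_fallback_is_passthrough(self, rng):
        coords = rng.random((20, 6))
        out = umap_embed(coords, seed=0, method="lsi")
        assert np.array_equal(out, coords[:, :2])

    def test_separated_types_stay_separated(self, rng):
        a = rng.normal(0, 0.3, size=(20, 5))
        b = rng.normal(6, 0.3, size=(20, 5))
        emb = umap_embed(np.vstack([a, b]), seed=3, method="umap")
        inter = np.linalg.norm(emb[:20].mean(0) - emb[20:].mean(0))
        intra = max(emb[:20].std(), emb[20:].std())
        assert inter > intra

    def test_umap_deterministic_under_seed(self, rng):
        X = rng.random((30, 4))
        e1 = umap_embed(X, seed=7, method="umap")
        e2 = umap_embed(X, seed=7, method="umap")
        assert np.array_equal(e1, e2)


class TestMetacells:
    def test_k_equals_m_single_metacell(self, rng):
        X = sp.csr_matrix(rng.integers(0, 5, size=(8, 6)))
        coords = rng.random((6, 3))
        with pytest.warns(UserWarning, match="single metacell"):
            meta = aggregate_metacells(X, coords, k=10)
        assert meta.n_metacells == 1
        assert np.array_equal(meta.counts.ravel(),
                              np.asarray(X.sum(axis=1)).ravel())

    def test_k1_zero_overlap_gives_distinct_singletons(self, rng):
        X = sp.csr_matrix(rng.integers(0, 5, size=(8, 10)))
        coords = rng.random((10, 2))
        meta = aggregate_metacells(X, coords, k=1, max_overlap=0.0, seed=0)
        members = [tuple(m) for m in meta.membership]
        assert len(set(members)) == len(members) == 10

    def test_aggregation_recomputation_oracle(self, dataset2, split2):
        sub = next(iter(split2.values()))
        from scse.coaccess import lsi_embed, tfidf_transform
        coords = lsi_embed(tfidf_transform(sub), n_components=10, seed=0)
        meta = aggregate_metacells(sub, coords, k=20, seed=0)
        X = np.asarray(sub.counts.todense())
        for j, mem in enumerate(meta.membership):
            assert len(mem) == 20
            assert np.array_equal(meta.counts[:, j], X[:, mem].sum(axis=1))


class TestGraphicalLasso:
    def test_matches_sklearn_with_uniform_penalty(self, rng):
        from sklearn.covariance import graphical_lasso as sk_glasso
        A = rng.random((8, 40))
        S = np.corrcoef(A)
        alpha = 0.1
        rho = np.full((8, 8), alpha)
        np.fill_diagonal(rho, 0.0)
        theta = graphical_lasso_penalty(S, rho)
        _, sk_prec = sk_glasso(S, alpha=alpha)
        assert np.allclose(theta, sk_prec, atol=2e-3)

    def test_infinite_penalty_forces_zero(self, rng):
        A = rng.random((4, 50))
        S = np.corrcoef(A)
        rho = np.zeros((4, 4))
        rho[0, 3] = rho[3, 0] = np.inf
        theta = graphical_lasso_penalty(S, rho)
        assert theta[0, 3] == 0.0


def _peaks_at(positions, chrom="chr1", width=500):
    return [GenomicInterval(chrom, p, p + width) for p in positions]


class TestCoaccessScores:
    def _planted(self, rng, n_meta=60):
        # two co-varying peaks 10 kb apart + two independent peaks
        latent = rng.gamma(2, 0.5, n_meta)
        counts = np.vstack([
            rng.poisson(20 * latent),
            rng.poisson(20 * latent),
            rng.poisson(20, n_meta),
            rng.poisson(20, n_meta),
        ]).astype(float)
        peaks = _peaks_at([100_000, 110_000, 300_000, 420_000])
        from scse.coaccess import MetacellMatrix
        meta = MetacellMatrix(counts, [np.array([i]) for i in range(n_meta)])
        return meta, peaks

    def test_planted_pair_outranks_background(self, rng):
        meta, peaks = self._planted(rng)
        pairs = coaccessibility_scores(meta, peaks)
        key = lambda p: (p.site_a.start, p.site_b.start)
        scores = {key(p): p.score for p in pairs}
        planted = scores[(100_000, 110_000)]
        assert planted > 0.5
        assert all(planted > v for k, v in scores.items()
                   if k != (100_000, 110_000))

    def test_no_pairs_across_chromosomes(self, rng):
        from scse.coaccess import MetacellMatrix
        counts = rng.poisson(10, size=(2, 30)).astype(float)
        peaks = [GenomicInterval("chr1", 1000, 1500),
                 GenomicInterval("chr2", 1000, 1500)]
        meta = MetacellMatrix(counts, [np.array([i]) for i in range(30)])
        assert coaccessibility_scores(meta, peaks) == []

    def test_no_pairs_beyond_max_dist(self, rng):
        from scse.coaccess import MetacellMatrix
        counts = rng.poisson(10, size=(2, 30)).astype(float)
        peaks = _peaks_at([0, 600_000])
        meta = MetacellMatrix(counts, [np.array([i]) for i in range(30)])
        assert coaccessibility_scores(meta, peaks, max_dist=500_000) == []

    def test_symmetric_and_unique_pairs(self, rng):
        meta, peaks = self._planted(rng)
        pairs = coaccessibility_scores(meta, peaks)
        seen = set()
        for p in pairs:
            ka = (p.site_a.chrom, p.site_a.start)
            kb = (p.site_b.chrom, p.site_b.start)
            assert ka < kb
            assert (ka, kb) not in seen
            seen.add((ka, kb))
            assert abs(p.score) <= 1.0

    def test_penalty_monotone_sparsity(self, rng):
        # at small sample sizes conditioning effects can push individual
        # partial correlations across the 0.1 line non-monotonically, so
        # the sparsity property is checked at a sample size where noise
        # correlations sit well below the threshold
        meta, peaks = self._planted(rng, n_meta=400)
        n_strong = []
        for scale in (0.1, 0.5, 2.0):
            pairs = coaccessibility_scores(meta, peaks, penalty_scale=scale)
            n_strong.append(sum(abs(p.score) >= 0.1 for p in pairs))
        assert n_strong[0] >= n_strong[1] >= n_strong[2]


class TestLinking:
    def _pairs(self):
        enh = GenomicInterval("chr1", 10_000, 10_500)
        prom = GenomicInterval("chr1", 50_000, 50_500)
        prom2 = GenomicInterval("chr1", 80_000, 80_500)
        far = GenomicInterval("chr1", 200_000, 200_500)
        return enh, prom, prom2, far

    def test_cutoff_and_single_promoter_side(self):
        enh, prom, prom2, far = self._pairs()
        windows = [GenomicInterval("chr1", 49_000, 51_000, name="geneA"),
                   GenomicInterval("chr1", 79_000, 81_000, name="geneB")]
        pairs = [CoAccessiblePair(enh, prom, 0.15, 40_000),
                 CoAccessiblePair(enh, far, 0.9, 190_000),   # no promoter
                 CoAccessiblePair(prom, prom2, 0.9, 30_000),  # both promoters
                 CoAccessiblePair(enh, prom2, 0.05, 70_000)]  # below cutoff
        links = link_enhancer_promoter(pairs, windows, cutoff=0.1)
        assert len(links) == 1
        assert links[0].gene == "geneA" and links[0].score == 0.15

    def test_toy_counting_example(self):
        enh, prom, prom2, far = self._pairs()
        windows = [GenomicInterval("chr1", 49_000, 51_000, name="geneA")]
        pairs = [CoAccessiblePair(enh, prom, 0.15, 1.0),
                 CoAccessiblePair(far, prom, 0.05, 1.0),
                 CoAccessiblePair(enh, far, 0.5, 1.0),
                 CoAccessiblePair(enh, prom2, 0.3, 1.0),
                 CoAccessiblePair(far, prom2, 0.2, 1.0)]
        links = link_enhancer_promoter(pairs, windows, cutoff=0.1)
        assert len(links) == 1
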