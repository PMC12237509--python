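import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from scse.consensus import (call_consensus_enhancers, cell_weights,
                            combined_peak_signal, shuffle_null_threshold,
                            tanimoto, tanimoto_matrix)
from scse.io import FragmentRecord, GeneModel, GenomicInterval, PeakByCellMatrix


class TestTanimoto:
    def test_identity_and_disjoint(self):
        assert tanimoto([1, 2, 3], [1, 2, 3]) == 1.0
        assert tanimoto([1, 0, 2], [0, 3, 0]) == 0.0

    def test_hand_value(self):
        assert tanimoto([1, 2, 0, 1], [0, 2, 1, 1]) == pytest.approx(5 / 7)

    def test_both_zero_warns_zero(self):
        with pytest.warns(UserWarning):
            assert tanimoto([0, 0], [0, 0]) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(arrays(np.int8, 25, elements=st.integers(0, 1)),
           arrays(np.int8, 25, elements=st.integers(0, 1)))
    def test_equals_jaccard_on_binary(self, a, b):
        sa, sb = set(np.flatnonzero(a)), set(np.flatnonzero(b))
        union = len(sa | sb)
        expected = len(sa & sb) / union if union else 0.0
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert tanimoto(a, b) == pytest.approx(expected)


class TestTanimotoMatrix:
    def test_identical_cells(self):
        X = sp.csr_matrix(np.array([[2, 2], [1, 1]]))
        assert np.allclose(tanimoto_matrix(X), 1.0)

    def test_matches_brute_force(self, rng):
        X = sp.csr_matrix(rng.integers(0, 5, size=(15, 8)))
        T = tanimoto_matrix(X)
        D = np.asarray(X.todense(), dtype=float)
        import warnings
        for i in range(8):
            for k in range(8):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    assert T[i, k] == pytest.approx(tanimoto(D[:, i], D[:, k]))

    def test_permutation_equivariance(self, rng):
        X = rng.integers(0, 4, size=(10, 6))
        perm = rng.permutation(6)
        T = tanimoto_matrix(sp.csr_matrix(X))
        Tp = tanimoto_matrix(sp.csr_matrix(X[:, perm]))
        assert np.allclose(Tp, T[np.ix_(perm, perm)])


class TestCellWeights:
    def test_two_identical_cells(self):
        assert np.allclose(cell_weights(np.ones((2, 2))), [0.5, 0.5])

    def test_hand_example_three_cells(self):
        # c1=(1,0), c2=(1,0), c3=(0,1): T12=1, T13=T23=0
        X = sp.csr_matrix(np.array([[1, 1, 0], [0, 0, 1]]))
        w = cell_weights(tanimoto_matrix(X))
        assert np.allclose(w, [0.5, 0.5, 0.0])

    def test_weights_sum_to_one(self, rng):
        for _ in range(5):
            X = sp.csr_matrix(rng.integers(0, 3, size=(30, 12)))
            w = cell_weights(tanimoto_matrix(X))
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w >= 0).all()

    def test_disjoint_cells_uniform_fallback(self):
        with pytest.warns(UserWarning, match="uniform"):
            w = cell_weights(np.eye(3))
        assert np.allclose(w, 1 / 3)


class TestCombinedSignal:
    def test_hand_value(self):
        X = sp.csr_matrix(np.array([[2, 4, 6]]))
        assert combined_peak_signal(X, [0.5, 0.5, 0.0])[0] == 3.0

    def test_uniform_weights_give_mean(self, rng):
        X = rng.integers(0, 9, size=(7, 5))
        s = combined_peak_signal(sp.csr_matrix(X), np.full(5, 1 / 5))
        assert np.allclose(s, X.mean(axis=1))

    def test_permutation_invariance(self, rng):
        X = rng.integers(0, 9, size=(7, 5))
        w = rng.random(5)
        perm = rng.permutation(5)
        a = combined_peak_signal(sp.csr_matrix(X), w)
        b = combined_peak_signal(sp.csr_matrix(X[:, perm]), w[perm])
        assert np.allclose(a, b)

    def test_monotonic_in_counts(self, rng):
        X = rng.integers(0, 5, size=(4, 6))
        w = np.abs(rng.random(6))
        w /= w.sum()
        before = combined_peak_signal(sp.csr_matrix(X), w)
        X2 = X.copy()
        X2[2, 3] += 5
        after = combined_peak_signal(sp.csr_matrix(X2), w)
        assert after[2] >= before[2]
        assert np.allclose(np.delete(after, 2), np.delete(before, 2))


class TestShuffleNull:
    def test_zero_fragments(self):
        peaks = [GenomicInterval("chr1", 0, 100)]
        t = shuffle_null_threshold([], peaks, ["c1", "c2"], [0.5, 0.5],
                                   {"chr1": 10_000})
        assert t == 0.0

    def test_deterministic_under_seed(self, dataset2, split2, frag_index2):
        sub = next(iter(split2.values()))
        w = cell_weights(tanimoto_matrix(sub))
        kw = dict(genome=dataset2.genome, n_shuffles=3, seed=42)
        t1 = shuffle_null_threshold(frag_index2, sub.peaks[:30], sub.barcodes,
                                    w, **kw)
        t2 = shuffle_null_threshold(frag_index2, sub.peaks[:30], sub.barcodes,
                                    w, **kw)
        assert t1 == t2

    def test_uniform_coverage_threshold_near_mean_signal(self):
        # constant-depth fragment tiling: shuffled peaks see the same
        # coverage as real peaks, so the null matches the real scores
        genome = {"chr1": 50_000}
        frags = [FragmentRecord("chr1", s, s + 100, bc)
                 for s in range(0, 49_900, 10) for bc in ("c1", "c2")]
        peaks = [GenomicInterval("chr1", 1000 * i, 1000 * i + 500)
                 for i in range(5, 15)]
        w = np.array([0.5, 0.5])
        from scse.intervals import FragmentIndex
        index = FragmentIndex(frags, ["c1", "c2"])
        real = np.array([index.count_in_region(p.chrom, p.start, p.end,
                                               per_cell=True) @ w
                         for p in peaks])
        t = shuffle_null_threshold(index, peaks, ["c1", "c2"], w, genome,
                                   n_shuffles=10, seed=0)
        assert t == pytest.approx(real.mean(), rel=0.05)


class TestCallConsensus:
    def _setup(self):
        # 6 cells; peaks: p0 broad support, p1 exonic, p2 low support
        peaks = [GenomicInterval("chr1", 1000, 1500, name="p0"),
                 GenomicInterval("chr1", 51_000, 51_500, name="p1"),
                 GenomicInterval("chr1", 101_000, 101_500, name="p2")]
        X = np.array([[5, 4, 3, 2, 1, 1],
                      [9, 9, 9, 9, 9, 9],
                      [1, 0, 0, 0, 0, 0]])
        m = PeakByCellMatrix(peaks, [f"c{i}" for i in range(6)], X)
        gene = GeneModel("g1", "g1", "chr1", "+", 50_000, 53_000,
                         exons=[GenomicInterval("chr1", 50_000, 53_000)])
        return m, [gene]

    def test_support_boundary_ceiling(self):
        m, genes = self._setup()
        w = np.full(6, 1 / 6)
        # peak nonzero in exactly ceil(6/3)=2 cells passes criterion i
        X = np.asarray(m.counts.todense())
        X[2, :2] = 1
        m2 = PeakByCellMatrix(m.peaks, m.barcodes, X)
        res = call_consensus_enhancers(m2, w, genes, None, [])
        assert res[2].qc_flags["support"]

    def test_exonic_peak_rejected_despite_score(self):
        m, genes = self._setup()
        res = call_consensus_enhancers(m, np.full(6, 1 / 6), genes, 0.0, [])
        by_name = {r.interval.name: r for r in res}
        assert not by_name["p1"].qc_flags["annotation"]
        assert not by_name["p1"].is_typical
        assert by_name["p0"].qc_flags["annotation"]

    def test_null_threshold_strict(self):
        m, genes = self._setup()
        res = call_consensus_enhancers(m, np.full(6, 1 / 6), genes,
                                       null_threshold=9.0, coaccess_links=[])
        by_name = {r.interval.name: r for r in res}
        assert not by_name["p1"].qc_flags["shuffle_null"]  # score == 9, not >
        assert not by_name["p0"].qc_flags["shuffle_null"]  # score < 9

    def test_missing_null_flags_and_warns(self):
        m, genes = self._setup()
        with pytest.warns(UserWarning, match="criterion iii"):
            res = call_consensus_enhancers(m, np.full(6, 1 / 6), genes,
                                           None, [])
        assert all(r.qc_flags["shuffle_null"] for r in res)

    def test_coaccess_criterion_uses_promoter_links(self):
        from scse.coaccess import CoAccessiblePair
        m, genes = self._setup()
        prom_peak = GenomicInterval("chr1", 49_000, 49_500, name="pp")
        peaks = m.peaks + [prom_peak]
        X = np.vstack([np.asarray(m.counts.todense()),
                       np.full(6, 3, dtype=int)])
        m2 = PeakByCellMatrix(peaks, m.barcodes, X)
        pair = CoAccessiblePair(m2.peaks[0], prom_peak, 0.25, 48_250.0)
        res = call_consensus_enhancers(m2, np.full(6, 1 / 6), genes, None,
                                       [pair])
        by_name = {r.interval.name: r for r in res}
        assert by_name["p0"].qc_flags["coaccessibility"]
        assert by_name["p0"].max_promoter_coaccess == 0.25
        assert not by_name["p2"].qc_flags["coaccessibility"]
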