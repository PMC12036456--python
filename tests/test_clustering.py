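from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

import helpers
from progsub import clustering as clu
from progsub.graph import GraphConfig, build_dpg
from test_graph import make_vec


def planted_sequences(rng, n_per=12, centers=None, dim=4, noise=0.4,
                      length_range=(6, 12)):
    """Well-separated sequence clusters around constant centers."""
    centers = centers if centers is not None else [
        np.zeros(dim), np.full(dim, 4.0), np.r_[np.full(dim // 2, -4.0), np.full(dim - dim // 2, 4.0)]
    ]
    dim = len(centers[0])
    seqs, labels = [], []
    for c, mu in enumerate(centers):
        for i in range(n_per):
            T = int(rng.integers(*length_range))
            vals = mu + rng.normal(0, noise, size=(T, dim))
            seqs.append(clu.EmbeddingSequence(f"c{c}_{i}", list(range(T)), vals))
            labels.append(c)
    return seqs, np.array(labels)


class TestDtwDistance:
    def test_identity_zero(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(7, 3))
        assert clu.dtw_distance(s, s) == 0.0

    def test_duplication_invariance(self):
        assert clu.dtw_distance([1, 2, 3], [1, 2, 2, 3]) == 0.0

    def test_single_point_matches_both(self):
        # the single point must align with both ends: |1-2| + |3-2|
        assert clu.dtw_distance([1, 3], [2]) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            clu.dtw_distance(np.zeros((0, 2)), np.ones((3, 2)))

    def test_dim_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            clu.dtw_distance(np.ones((3, 2)), np.ones((3, 4)))

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=(int(rng.integers(1, 8)), 3))
            b = rng.normal(size=(int(rng.integers(1, 8)), 3))
            d = clu.dtw_distance(a, b)
            assert d >= 0
            assert d == pytest.approx(clu.dtw_distance(b, a))

    def test_singleton_sequences_reduce_to_pointwise_metric(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.normal(size=3), rng.normal(size=3)
            assert clu.dtw_distance(a[None, :], b[None, :]) == pytest.approx(
                float(np.linalg.norm(a - b)))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            dim = int(rng.integers(1, 4))
            a = rng.normal(size=(int(rng.integers(1, 5)), dim))
            b = rng.normal(size=(int(rng.integers(1, 5)), dim))
            assert clu.dtw_distance(a, b) == pytest.approx(
                helpers.brute_force_dtw(a, b), abs=1e-10)


class TestBarycenter:
    def test_singleton_is_resampled_self(self):
        s = np.array([[0.0], [1.0], [2.0], [3.0]])
        c = clu.dtw_barycenter([s])
        assert c.shape == s.shape
        assert np.allclose(c, s)

    def test_two_identical_sequences(self):
        s = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        assert np.allclose(clu.dtw_barycenter([s, s.copy()]), s)

    def test_refinement_never_increases_cost(self):
        rng = np.random.default_rng(4)
        seqs = [rng.normal(size=(int(rng.integers(5, 10)), 3)) for _ in range(6)]
        init = clu._resample(seqs[0], 7)
        cost_prev = sum(clu.dtw_distance(m, init) for m in seqs)
        centroid, cost = clu._dba_refine(seqs, init, n_iter=10)
        assert cost <= cost_prev + 1e-9
        # and the reported cost is the actual summed DTW
        assert cost == pytest.approx(sum(clu.dtw_distance(m, centroid) for m in seqs))


class TestTsKmeans:
    def test_k_equals_n_zero_objective(self):
        rng = np.random.default_rng(0)
        seqs = [rng.normal(size=(5, 2)) + 10 * i for i in range(4)]
        res = clu.tskmeans(seqs, k=4, seed=0, n_init=2)
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_two_identical_groups_perfect_split(self):
        a = np.zeros((6, 2))
        b = np.full((6, 2), 9.0)
        seqs = [a, a.copy(), a.copy(), b, b.copy(), b.copy()]
        res = clu.tskmeans(seqs, k=2, seed=0)
        assert res.objective == pytest.approx(0.0, abs=1e-9)
        assert len(set(res.assignments[:3])) == 1
        assert len(set(res.assignments[3:])) == 1
        assert res.assignments[0] != res.assignments[3]

    def test_planted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(10)
        seqs, labels = planted_sequences(rng)
        res = clu.tskmeans(seqs, k=3, seed=1)
        assert adjusted_rand_score(labels, res.assignments) >= 0.9

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(11)
        seqs, _ = planted_sequences(rng, noise=1.5)
        res = clu.tskmeans(seqs, k=3, seed=2)
        trace = res.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
        assert res.objective == trace[-1]

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError, match="exceeds"):
            clu.tskmeans([np.zeros((3, 1))], k=2)

    def test_relabeling_invariance_of_indices(self):
        """SS, DBI and J are invariant under a cluster-label permutation."""
        rng = np.random.default_rng(12)
        seqs, _ = planted_sequences(rng)
        res = clu.tskmeans(seqs, k=3, seed=3)
        perm = np.array([2, 0, 1])
        relabeled = perm[res.assignments]
        D = clu.pairwise_dtw(seqs)
        assert clu.silhouette_dtw(seqs, res.assignments, D) == pytest.approx(
            clu.silhouette_dtw(seqs, relabeled, D))
        cents_perm = [res.centroids[int(np.flatnonzero(perm == c)[0])] for c in range(3)]
        assert clu.davies_bouldin_dtw(seqs, res.assignments, res.centroids) == pytest.approx(
            clu.davies_bouldin_dtw(seqs, relabeled, cents_perm))
        j1 = sum(clu.dtw_distance(s, res.centroids[c]) for s, c in zip(seqs, res.assignments))
        j2 = sum(clu.dtw_distance(s, cents_perm[c]) for s, c in zip(seqs, relabeled))
        assert j1 == pytest.approx(j2)


class TestSilhouette:
    def test_tight_far_clusters_high_score(self):
        rng = np.random.default_rng(5)
        seqs, labels = planted_sequences(rng, n_per=8, noise=0.05,
                                         centers=[np.zeros(3), np.full(3, 50.0)])
        assert clu.silhouette_dtw(seqs, labels) > 0.9

    def test_identical_sequences_forced_split_zero(self):
        s = np.ones((4, 2))
        seqs = [s.copy() for _ in range(6)]
        labels = [0, 0, 0, 1, 1, 1]
        assert clu.silhouette_dtw(seqs, labels) == 0.0

    def test_single_cluster_undefined(self):
        with pytest.raises(ValueError, match="single cluster"):
            clu.silhouette_dtw([np.zeros((2, 1))] * 3, [0, 0, 0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        seqs, labels = planted_sequences(rng, n_per=5, noise=2.0)
        D = clu.pairwise_dtw(seqs)
        assert clu.silhouette_dtw(seqs, labels, D) == pytest.approx(
            helpers.brute_force_silhouette(D, labels))

    def test_singleton_cluster_contributes_zero(self):
        rng = np.random.default_rng(7)
        seqs = [rng.normal(size=(4, 2)) for _ in range(5)]
        labels = [0, 0, 0, 0, 1]  # cluster 1 is a singleton
        D = clu.pairwise_dtw(seqs)
        got = clu.silhouette_dtw(seqs, labels, D)
        expected = helpers.brute_force_silhouette(D, labels)
        assert got == pytest.approx(expected)


class TestDaviesBouldin:
    def test_zero_scatter_distinct_centroids(self):
        a, b = np.zeros((3, 2)), np.full((3, 2), 5.0)
        seqs = [a, a.copy(), b, b.copy()]
        assert clu.davies_bouldin_dtw(seqs, [0, 0, 1, 1], [a, b]) == 0.0

    def test_monotone_in_scatter(self):
        rng = np.random.default_rng(8)
        centers = [np.zeros(2), np.full(2, 10.0)]

        def dbi(noise):
            seqs, labels = planted_sequences(rng, n_per=6, noise=noise,
                                             centers=centers)
            cents = [np.tile(c, (8, 1)) for c in centers]
            return clu.davies_bouldin_dtw(seqs, labels, cents)

        assert dbi(0.1) < dbi(1.0)

    def test_coincident_centroids_error(self):
        s = np.zeros((3, 2))
        with pytest.raises(ValueError, match="coincident"):
            clu.davies_bouldin_dtw([s, s.copy()], [0, 1], [s, s.copy()])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        seqs, labels = planted_sequences(rng, n_per=5, noise=1.0)
        res = clu.tskmeans(seqs, k=3, seed=0, n_init=2)
        got = clu.davies_bouldin_dtw(seqs, res.assignments, res.centroids)
        scatters = []
        cdists = [[0.0] * 3 for _ in range(3)]
        for c in range(3):
            members = [seqs[i] for i in np.flatnonzero(res.assignments == c)]
            scatters.append(np.mean([clu.dtw_distance(m, res.centroids[c]) for m in members]))
            for c2 in range(3):
                if c != c2:
                    cdists[c][c2] = clu.dtw_distance(res.centroids[c], res.centroids[c2])
        assert got == pytest.approx(helpers.brute_force_dbi(scatters, cdists))


class TestSelectK:
    def test_scan_rows_and_planted_k(self):
        rng = np.random.default_rng(13)
        seqs, _ = planted_sequences(rng, n_per=6)
        report = clu.select_k(seqs, k_range=range(2, 7), seed=0, n_init=3)
        assert [r["k"] for r in report.rows] == [2, 3, 4, 5, 6]
        planted = next(r for r in report.rows if r["k"] == 3)
        assert planted["admissible"]
        assert report.chosen_k == 3

    def test_full_scan_has_nine_rows(self):
        rng = np.random.default_rng(14)
        seqs, _ = planted_sequences(rng, n_per=5, length_range=(3, 5))
        report = clu.select_k(seqs, k_range=range(2, 11), seed=0, n_init=1, max_iter=5)
        assert len(report.rows) == 9

    def test_degenerate_identical_sequences_warns(self):
        seqs = [np.ones((3, 2)) for _ in range(8)]
        with pytest.warns(UserWarning, match="admissible"):
            report = clu.select_k(seqs, k_range=range(2, 4), seed=0, n_init=1)
        assert report.chosen_k is None
        assert not any(r["admissible"] for r in report.rows)


class TestCollectSequences:
    def _graph(self):
        vecs = [make_vec("P1", d, (0,)) for d in (0, 30, 60, 90, 120)]
        vecs += [make_vec("P2", d, (1,)) for d in (5, 50)]
        return build_dpg(vecs, GraphConfig(k=1))

    def test_lengths_and_order(self):
        g = self._graph()
        emb = np.arange(g.n_nodes * 2, dtype=float).reshape(g.n_nodes, 2)
        seqs = clu.collect_sequences(emb, g)
        assert [s.patient_id for s in seqs] == ["P1", "P2"]
        assert [len(s.dates) for s in seqs] == [5, 2]
        for s in seqs:
            assert s.dates == sorted(s.dates)

    def test_missing_embedding_error(self):
        g = self._graph()
        emb = np.zeros((g.n_nodes, 2))
        emb[3] = np.nan
        with pytest.raises(ValueError, match="node 3"):
            clu.collect_sequences(emb, g)

    def test_row_count_mismatch(self):
        g = self._graph()
        with pytest.raises(ValueError, match="rows"):
            clu.collect_sequences(np.zeros((2, 2)), g)
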