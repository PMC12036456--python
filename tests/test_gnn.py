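from __future__ import annotations

import math
from datetime import date, timedelta

import numpy as np
import pytest
import scipy.sparse as sp

import helpers
from progsub import _autodiff as ad
from progsub import gnn
from progsub.featurize import STAGES
from progsub.graph import GraphConfig, ProgressionGraph, build_dpg
from test_graph import make_vec


def random_digraph(rng, n):
    A = (rng.random((n, n)) < 0.25).astype(float) * rng.uniform(0.1, 1.0, (n, n))
    np.fill_diagonal(A, 0.0)
    return sp.csr_matrix(A)


class TestMagneticLaplacian:
    def test_q_zero_symmetric_matches_standard_laplacian(self):
        rng = np.random.default_rng(0)
        A = random_digraph(rng, 8)
        A = (A + A.T) * 0.5  # symmetric
        L = gnn.magnetic_laplacian(A, q=0.0)
        assert np.abs(L.imag).max() == 0.0
        # standard symmetric-normalized Laplacian with self-loops
        As = A.toarray() + np.eye(8)
        d = As.sum(axis=1)
        Dinv = np.diag(1 / np.sqrt(d))
        Lref = np.eye(8) - Dinv @ As @ Dinv
        assert np.abs(L.real - Lref).max() < 1e-12

    def test_single_edge_phase_at_quarter_q(self):
        # theta = 2*pi*q*(A - A^T): a unit edge u->v at q = 0.25 gives
        # theta_uv = pi/2, so the phase factor is the imaginary unit and the
        # (v,u) entry is its conjugate
        A = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
        theta = 2 * np.pi * 0.25 * (A - A.T).toarray()
        assert theta[0, 1] == pytest.approx(np.pi / 2)
        assert np.exp(1j * theta[0, 1]) == pytest.approx(1j)
        assert np.exp(1j * theta[1, 0]) == pytest.approx(-1j)
        L = gnn.magnetic_laplacian(A, q=0.25)
        assert L[0, 1] == pytest.approx(np.conj(L[1, 0]))
        assert L[0, 1].real == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_hermitian_real_spectrum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        A = random_digraph(rng, n)
        q = float(rng.uniform(0, 0.5))
        L = gnn.magnetic_laplacian(A, q)
        assert np.abs(L - L.conj().T).max() < 1e-10
        ev = np.linalg.eigvals(L)
        assert np.abs(ev.imag).max() < 1e-10

    def test_negative_weights_rejected(self):
        A = sp.csr_matrix(np.array([[0.0, -1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            gnn.magnetic_laplacian(A, 0.25)


class TestLayerForward:
    def test_isolated_nodes_depend_only_on_self(self):
        g = ProgressionGraph(
            node_patients=["A", "B"], node_dates=[date(2015, 1, 1)] * 2, edges=[]
        )
        op = gnn.build_operator(g, gnn.EncoderConfig(variant="gcn"))
        W = {"W": ad.Tensor(np.eye(3)), "b": ad.Tensor(np.zeros(3))}
        X = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        out = gnn.gnn_layer_forward(X, op, W, "gcn").value
        assert np.allclose(out, X)  # self-loop normalization is identity

    def test_identical_features_regular_graph_identical_outputs(self):
        # directed 4-cycle: in/out degree 1 everywhere
        edges = [(0, 1, 1, "similarity"), (1, 2, 1, "similarity"),
                 (2, 3, 1, "similarity"), (3, 0, 0, "similarity")]
        d0 = date(2015, 1, 1)
        g = ProgressionGraph(node_patients=list("ABCD"),
                             node_dates=[d0, d0 + timedelta(days=1),
                                         d0 + timedelta(days=2), d0 + timedelta(days=2)],
                             edges=[])
        g.edges = edges  # hand-built cycle, not validated chronology
        cfg = gnn.EncoderConfig(variant="gcn", weight_mode="unweighted")
        op = gnn.build_operator(g, cfg)
        X = np.tile([1.0, -2.0], (4, 1))
        params = {"W": ad.Tensor(np.array([[0.5, 1.0], [0.2, -0.3]])),
                  "b": ad.Tensor(np.array([0.1, 0.0]))}
        out = gnn.gnn_layer_forward(X, op, params, "gcn").value
        assert np.allclose(out, out[0])

    @pytest.mark.parametrize("seed", range(3))
    def test_magnet_q0_equals_gcn_on_symmetrized(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        d0 = date(2015, 1, 1)
        g = ProgressionGraph(node_patients=[f"P{i}" for i in range(n)],
                             node_dates=[d0 + timedelta(days=i) for i in range(n)],
                             edges=[])
        g.edges = [(i, j, j - i, "similarity")
                   for i in range(n) for j in range(i + 1, n) if rng.random() < 0.3]
        X = rng.normal(size=(n, 5))
        W = ad.Tensor(rng.normal(size=(5, 4)))
        b = ad.Tensor(rng.normal(size=4))
        cfg0 = gnn.EncoderConfig(variant="magnet", q=0.0)
        Pr, Pi = gnn.build_operator(g, cfg0)
        hr, hi = gnn.gnn_layer_forward(
            (ad.Tensor(X), ad.Tensor(np.zeros_like(X))), (Pr, Pi),
            {"W": W, "b": b}, "magnet")
        gcn_out = gnn.gnn_layer_forward(
            X, gnn.build_operator(g, gnn.EncoderConfig(variant="gcn")),
            {"W": W, "b": b}, "gcn")
        assert np.abs(hr.value - gcn_out.value).max() < 1e-8
        assert np.abs(hi.value).max() == 0.0


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy_value(self):
        p = np.array([[0.5, 0.25, 0.25]])
        assert gnn.focal_loss(p, np.array([0]), gamma=0.0) == pytest.approx(math.log(2))

    def test_perfect_prediction_zero(self):
        p = np.array([[1.0, 0.0, 0.0]])
        for g in (0.0, 1.0, 2.0, 5.0):
            assert gnn.focal_loss(p, np.array([0]), gamma=g) == 0.0

    def test_gamma_two_hand_value(self):
        p = np.array([[0.9, 0.05, 0.05]])
        expected = 0.01 * -math.log(0.9)
        assert gnn.focal_loss(p, np.array([0]), gamma=2.0) == pytest.approx(expected)

    def test_equals_cross_entropy_at_gamma_zero(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=200)
        y = rng.integers(0, 3, size=200)
        assert abs(gnn.focal_loss(p, y, 0.0) - gnn.cross_entropy(p, y)) < 1e-12

    def test_stage_labels_accepted_and_validated(self):
        p = np.array([[0.2, 0.5, 0.3]])
        assert gnn.focal_loss(p, np.array(["MCI"]), 0.0) == pytest.approx(-math.log(0.5))
        with pytest.raises(ValueError, match="continuum"):
            gnn.focal_loss(p, np.array(["remission"]), 0.0)


class TestSplits:
    def test_ten_patients_split_7_1_2(self):
        ids = [f"P{i}" for i in range(10)]
        split = gnn.split_by_patient(ids, seed=0)
        counts = {s: sum(1 for v in split.values() if v == s) for s in ("train", "val", "test")}
        assert counts == {"train": 7, "val": 1, "test": 2}

    def test_same_seed_same_partition(self):
        ids = [f"P{i}" for i in range(25)]
        assert gnn.split_by_patient(ids, seed=3) == gnn.split_by_patient(ids, seed=3)

    def test_nodes_follow_their_patient(self):
        vecs = [make_vec(f"P{i}", d, (i % 6,)) for i in range(6) for d in (0, 30, 60)]
        g = build_dpg(vecs, GraphConfig(k=2))
        split = gnn.split_by_patient(g.node_patients, ratios=(0.5, 0.25, 0.25), seed=1)
        masks = gnn.node_masks(g, split)
        for i, pid in enumerate(g.node_patients):
            role = split[pid]
            assert masks.train[i] == (role == "train")
            assert masks.val[i] == (role == "val")
            assert masks.test[i] == (role == "test")

    def test_errors(self):
        with pytest.raises(ValueError, match="sum to 1"):
            gnn.split_by_patient(["a"], ratios=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError, match="cannot split"):
            gnn.split_by_patient(["a", "b"], ratios=(0.4, 0.3, 0.3))


def planted_two_block_graph(n_patients=10, per_patient=3, seed=0):
    """Small graph whose next-stage labels are determined by a feature block."""
    rng = np.random.default_rng(seed)
    vecs = []
    for i in range(n_patients):
        block = i % 2
        for j in range(per_patient):
            bits = {0, 1} if block == 0 else {4, 5}
            extra = {int(rng.integers(6, 8))}
            stage = "MCI" if block == 0 else "AD"
            vecs.append(make_vec(f"P{i:02d}", j * 40 + int(rng.integers(5)),
                                 bits | extra, stage=stage,
                                 next_stage=None if j == per_patient - 1 else stage))
    return build_dpg(vecs, GraphConfig(k=3))


class TestEncoder:
    def test_probabilities_sum_to_one_and_embedding_dims(self):
        g = planted_two_block_graph()
        for skip in (False, True):
            cfg = gnn.EncoderConfig(embedding_size=8, skip_aggregate=skip, epochs=1)
            enc = gnn.Encoder(g, cfg)
            emb, probs = enc.forward(enc.init_params())
            assert np.allclose(probs.value.sum(axis=1), 1.0)
            expected = 8 + (g.features.shape[1] if skip else 0)
            assert emb.shape[1] == expected == enc.embedding_dim

    def test_forward_deterministic(self):
        g = planted_two_block_graph()
        cfg = gnn.EncoderConfig(embedding_size=8, seed=5)
        enc = gnn.Encoder(g, cfg)
        params = enc.init_params()
        e1, p1 = enc.forward(params)
        e2, p2 = enc.forward(params)
        assert np.array_equal(e1.value, e2.value)
        assert np.array_equal(p1.value, p2.value)

    @pytest.mark.parametrize("variant", ["magnet", "gcn", "gat", "graphsage"])
    def test_variants_run_and_overfit_planted_blocks(self, variant):
        """Block-separable labels are learnable to high test AUROC."""
        g = planted_two_block_graph(n_patients=10, per_patient=3, seed=1)
        cfg = gnn.EncoderConfig(variant=variant, embedding_size=8, epochs=120,
                                patience=200, seed=0, skip_aggregate=False)
        params, report, emb = gnn.train_encoder(g, cfg)
        assert report["final_train_loss"] <= report["initial_train_loss"]
        assert report["macro"]["auroc"] >= 0.95

    def test_training_reproducible(self):
        g = planted_two_block_graph()
        cfg = gnn.EncoderConfig(embedding_size=8, epochs=10, seed=9)
        _, r1, e1 = gnn.train_encoder(g, cfg)
        _, r2, e2 = gnn.train_encoder(g, cfg)
        assert np.array_equal(e1, e2)
        assert r1["final_train_loss"] == r2["final_train_loss"]

    def test_metrics_match_hand_confusion_matrix(self):
        y = np.array([0, 0, 1, 1, 2, 2, 2, 0])
        probs = np.array([
            [0.8, 0.1, 0.1], [0.2, 0.7, 0.1], [0.1, 0.8, 0.1], [0.1, 0.7, 0.2],
            [0.1, 0.1, 0.8], [0.6, 0.2, 0.2], [0.0, 0.1, 0.9], [0.7, 0.2, 0.1],
        ])
        got = gnn.classification_metrics(y, probs)
        expected = helpers.hand_confusion_metrics(y, probs.argmax(axis=1), 3)
        for c, name in enumerate(STAGES):
            for m in ("sensitivity", "specificity", "precision"):
                assert got["per_class"][name][m] == pytest.approx(expected[c][m])

    def test_divergence_reported_with_epoch(self):
        g = planted_two_block_graph()
        cfg = gnn.EncoderConfig(embedding_size=8, epochs=30, learning_rate=1e12, seed=0)
        with pytest.raises(RuntimeError, match="epoch"):
            gnn.train_encoder(g, cfg)


class TestEdgeWeights:
    def test_inverse_year_mapping(self):
        w = gnn.normalize_edge_weights(np.array([0.0, 365.0, 3650.0]))
        assert w == pytest.approx([1.0, 0.5, 1.0 / 11.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            gnn.normalize_edge_weights(np.array([-1.0]))
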