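"""GraRep graph embedding against hand-worked values and a brute-force oracle."""

import numpy as np
import pytest

from mirlink.grarep import (
    GraRepConfig,
    build_graph,
    grarep_embed,
    kstep_log_matrix,
    kstep_representation,
    transition_matrix,
)


def brute_force_grarep(S, K, d, beta, eps=1e-9, use_gamma=True):
    """Independent dense implementation of the embedding algorithm:
    A = D^-1 S; per k: X^k = max(0, log(A^k/Gamma + eps) - log beta),
    W^k = U_d diag(sigma_d)^{1/2} with the largest-|entry|-positive sign
    convention; W = [W^1 | ... | W^K]."""
    deg = S.sum(axis=1)
    A = np.zeros_like(S, dtype=float)
    for i in range(len(S)):
        if deg[i] > 0:
            A[i] = S[i] / deg[i]
    blocks = []
    Ak = np.eye(len(S))
    for _k in range(K):
        Ak = Ak @ A
        if use_gamma:
            gamma = Ak.sum(axis=0)
            ratio = np.zeros_like(Ak)
            nz = gamma > 0
            ratio[:, nz] = Ak[:, nz] / gamma[nz]
        else:
            ratio = Ak
        X = np.log(ratio + eps) - np.log(beta)
        X[X < 0] = 0.0
        U, s, _ = np.linalg.svd(X)
        Ud, sd = U[:, :d].copy(), s[:d]
        for j in range(d):
            if Ud[np.argmax(np.abs(Ud[:, j])), j] < 0:
                Ud[:, j] *= -1
        blocks.append(Ud * np.sqrt(sd))
    return np.concatenate(blocks, axis=1)


class TestGraph:
    def test_single_edge(self):
        g = build_graph([("mi1", "g1")])
        assert g.n_nodes == 2
        assert np.array_equal(g.S, [[0, 1], [1, 0]])

    def test_degree_and_duplicates(self):
        g = build_graph([("mi1", "g1"), ("mi1", "g2"), ("mi1", "g1")])
        i = g.node_index()["mi1"]
        assert g.S[i].sum() == 2  # duplicate pair collapsed

    def test_node_order_mirnas_then_mrnas_sorted(self):
        g = build_graph([("b", "z"), ("a", "y")])
        assert g.node_ids == ("a", "b", "y", "z")

    def test_role_clash_rejected(self):
        with pytest.raises(ValueError):
            build_graph([("x", "g1"), ("mi1", "x")])


class TestTransition:
    def test_path_graph_hand_computed(self):
        g = build_graph([("mi1", "g1"), ("mi2", "g1")])
        A = transition_matrix(g)
        # node order mi1, mi2, g1; g1 has degree 2
        assert np.allclose(A, [[0, 0, 1], [0, 0, 1], [0.5, 0.5, 0]])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        pairs = [(f"mi{i}", f"m{j}") for i in range(5) for j in range(7) if rng.random() < 0.4]
        A = transition_matrix(build_graph(pairs))
        sums = A.sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))


class TestLogMatrix:
    def test_single_edge_hand_computed(self):
        # A=[[0,1],[1,0]], Gamma=[1,1], beta=0.5 -> off-diagonals log 2
        g = build_graph([("mi1", "g1")])
        X = kstep_log_matrix(transition_matrix(g), 1, GraRepConfig(K=1, d=1, beta=0.5, eps=1e-12))
        assert np.allclose(X, [[0, np.log(2)], [np.log(2), 0]], atol=1e-9)

    def test_negative_entries_clipped(self):
        # entry probability 0.25 with beta=1 -> log 0.25 < 0 -> clipped to 0
        A = np.full((4, 4), 0.25)
        X = kstep_log_matrix(A, 1, GraRepConfig(beta=1.0, eps=1e-12))
        assert np.all(X == 0)

    def test_k1_power_identity(self):
        g = build_graph([("mi1", "g1"), ("mi1", "g2"), ("mi2", "g2")])
        A = transition_matrix(g)
        cfg = GraRepConfig(beta=1e-6, eps=1e-9)  # tiny beta: nothing clipped
        X1 = kstep_log_matrix(A, 1, cfg)
        assert np.allclose(np.exp(X1 + np.log(cfg.beta)) - cfg.eps, A / A.sum(axis=0), atol=1e-5)

    def test_nonnegative_after_clipping(self):
        rng = np.random.default_rng(1)
        pairs = [(f"mi{i}", f"m{j}") for i in range(4) for j in range(5) if rng.random() < 0.5]
        A = transition_matrix(build_graph(pairs))
        for k in (1, 2, 3):
            assert kstep_log_matrix(A, k, GraRepConfig()).min() >= 0


class TestSVDStep:
    def test_zero_matrix(self):
        assert np.allclose(kstep_representation(np.zeros((3, 3)), 2), 0)

    def test_diagonal_closed_form(self):
        W = kstep_representation(np.diag([2.0, 1.0]), 1)
        assert np.allclose(W, [[np.sqrt(2)], [0.0]], atol=1e-12)

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.standard_normal((5, 5)))
        U, s, Vt = np.linalg.svd(X)
        assert np.allclose((U * s) @ Vt, X, atol=1e-10)

    def test_nonfinite_rejected(self):
        X = np.ones((3, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            kstep_representation(X, 1)


class TestEmbed:
    def test_shape_and_k1_identity(self):
        g = build_graph([("mi1", "g1"), ("mi2", "g1"), ("mi2", "g2")])
        cfg = GraRepConfig(K=3, d=2)
        emb = grarep_embed(g, cfg)
        assert emb.W.shape == (g.n_nodes, 6)
        one = grarep_embed(g, GraRepConfig(K=1, d=2))
        assert np.allclose(one.W, emb.block(1))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_mi, n_m = rng.integers(3, 6), rng.integers(3, 7)
        pairs = [
            (f"mi{i}", f"m{j}")
            for i in range(n_mi)
            for j in range(n_m)
            if rng.random() < 0.5
        ]
        if not pairs:
            pairs = [("mi0", "m0")]
        g = build_graph(pairs)
        cfg = GraRepConfig(K=4, d=2, beta=1.0 / g.n_nodes)
        W = grarep_embed(g, cfg).W
        W_oracle = brute_force_grarep(g.S, K=4, d=2, beta=1.0 / g.n_nodes)
        assert np.allclose(np.abs(W), np.abs(W_oracle), atol=1e-8)

    def test_permutation_equivariance(self):
        pairs = [("mi1", "g1"), ("mi2", "g1"), ("mi3", "g2"), ("mi1", "g2")]
        cfg = GraRepConfig(K=2, d=2)
        emb = grarep_embed(build_graph(pairs), cfg)
        # relabeling ids permutes the sorted node order; rows must follow
        ren = {"mi1": "mi9", "mi2": "mi2", "mi3": "mi3", "g1": "g1", "g2": "g2"}
        emb2 = grarep_embed(build_graph([(ren[a], ren[b]) for a, b in pairs]), cfg)
        lut2 = {nid: row for nid, row in zip(emb2.node_ids, emb2.W)}
        for nid, row in zip(emb.node_ids, emb.W):
            assert np.allclose(np.abs(row), np.abs(lut2[ren[nid]]), atol=1e-8)

    def test_literal_variant_differs(self):
        g = build_graph([("mi1", "g1"), ("mi2", "g1"), ("mi2", "g2")])
        with_gamma = grarep_embed(g, GraRepConfig(K=2, d=2, use_gamma=True))
        literal = grarep_embed(g, GraRepConfig(K=2, d=2, use_gamma=False))
        assert not np.allclose(with_gamma.W, literal.W)
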