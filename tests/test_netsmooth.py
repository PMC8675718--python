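"""Network construction, adjacency normalisation and diffusion."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cellmatch.netsmooth import (GeneNetwork, normalize_adjacency, propagate,
                                 smooth_alterations)


def net_from(edges, nodes=None):
    return GeneNetwork.from_edges(edges, nodes=nodes)


class TestNormalizeAdjacency:
    def test_single_edge_gives_unit_offdiagonal(self):
        W = normalize_adjacency(net_from([("g1", "g2")])).toarray()
        np.testing.assert_allclose(W, [[0, 1], [1, 0]])

    def test_triangle_offdiagonals_are_half(self):
        # degrees are all 2, so D^(-1/2) A D^(-1/2) has off-diagonals 1/2
        W = normalize_adjacency(
            net_from([("a", "b"), ("b", "c"), ("a", "c")])).toarray()
        expected = np.full((3, 3), 0.5)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(W, expected)

    def test_isolated_node_row_and_column_zero(self):
        W = normalize_adjacency(
            net_from([("a", "b")], nodes=["a", "b", "lonely"])).toarray()
        assert (W[2, :] == 0).all() and (W[:, 2] == 0).all()

    def test_symmetric_for_weighted_graph(self):
        W = normalize_adjacency(
            net_from([("a", "b", 2.0), ("b", "c", 0.5), ("c", "d", 3.0)]))
        np.testing.assert_allclose(W.toarray(), W.toarray().T)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(GeneNetwork.from_edges([], nodes=["a"]))

    def test_self_loops_dropped_on_construction(self):
        net = net_from([("a", "a"), ("a", "b")])
        assert net.n_edges == 1


class TestPropagate:
    def test_two_node_path_closed_form(self):
        # (1-a)(I - aW)^(-1) applied to [1, 0] with a = 0.5 gives [2/3, 1/3]
        W = normalize_adjacency(net_from([("g1", "g2")]))
        F, _ = propagate(np.array([[1.0, 0.0]]), W, alpha=0.5)
        np.testing.assert_allclose(F, [[2 / 3, 1 / 3]], atol=1e-6)

    def test_small_alpha_approaches_input(self):
        W = normalize_adjacency(net_from([("g1", "g2")]))
        F, _ = propagate(np.array([[1.0, 0.0]]), W, alpha=1e-9)
        np.testing.assert_allclose(F, [[1.0, 0.0]], atol=1e-8)

    def test_zero_row_stays_zero(self):
        W = normalize_adjacency(net_from([("g1", "g2"), ("g2", "g3")]))
        F, _ = propagate(np.zeros((1, 3)), W, alpha=0.5)
        np.testing.assert_array_equal(F, np.zeros((1, 3)))

    @pytest.mark.parametrize("bad_alpha", [0.0, 1.0, -0.2, 1.5])
    def test_alpha_outside_unit_interval_rejected(self, bad_alpha):
        W = normalize_adjacency(net_from([("g1", "g2")]))
        with pytest.raises(ValueError):
            propagate(np.ones((1, 2)), W, alpha=bad_alpha)

    def test_iterative_matches_direct_linear_solve(self, rng):
        # fixed point is (1-a) F0 (I - aW)^(-1) for random small networks
        for trial in range(5):
            n = int(rng.integers(5, 51))
            edges = set()
            for i in range(1, n):
                edges.add((f"g{i}", f"g{int(rng.integers(0, i))}"))
            for _ in range(n):
                a, b = rng.integers(0, n, 2)
                if a != b:
                    edges.add((f"g{a}", f"g{b}"))
            W = normalize_adjacency(net_from(sorted(edges)))
            F0 = (rng.random((3, n)) < 0.1).astype(float)
            alpha = float(rng.uniform(0.2, 0.8))
            F_iter, _ = propagate(F0, W, alpha=alpha, tol=1e-9)
            A = np.eye(n) - alpha * W.toarray()
            F_direct = (1 - alpha) * np.linalg.solve(A.T, F0.T).T
            np.testing.assert_allclose(F_iter, F_direct, atol=1e-5)

    def test_neighbour_score_nondecreasing_in_alpha(self):
        # on a 3-node path with a seed at one end, more mixing weight means
        # more signal at the direct neighbour
        W = normalize_adjacency(net_from([("a", "b"), ("b", "c")]))
        F0 = np.array([[1.0, 0.0, 0.0]])
        prev = -np.inf
        for alpha in (0.1, 0.3, 0.5, 0.7, 0.9):
            F, _ = propagate(F0, W, alpha=alpha, tol=1e-10)
            assert F[0, 1] >= prev
            prev = F[0, 1]

    def test_nonconvergence_warns_but_returns(self):
        W = normalize_adjacency(net_from([("g1", "g2")]))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            F, n_iter = propagate(np.array([[1.0, 0.0]]), W, alpha=0.99,
                                  tol=1e-14, max_iter=3)
        assert n_iter == 3 and np.isfinite(F).all()


class TestSmoothAlterations:
    @staticmethod
    def binary_frame(values, samples, genes):
        return pd.DataFrame(values, index=samples, columns=genes)

    def test_off_network_passthrough_equals_input(self):
        net = net_from([("x1", "x2")])
        mat = self.binary_frame([[1, 0], [0, 1]], ["s1", "s2"], ["gA", "gB"])
        sm_mut, sm_cnv = smooth_alterations(mat, mat, net)
        pd.testing.assert_frame_equal(sm_mut.values, mat.astype(float))

    def test_zero_overlap_strict_mode_raises(self):
        net = net_from([("x1", "x2")])
        mat = self.binary_frame([[1, 0], [0, 1]], ["s1", "s2"], ["gA", "gB"])
        with pytest.raises(ValueError, match="no genes overlap"):
            smooth_alterations(mat, mat, net, off_network="drop")

    def test_single_seed_spreads_through_component(self):
        net = net_from([("a", "b"), ("b", "c"), ("c", "d")])
        mat = self.binary_frame([[1, 0, 0, 0], [0, 0, 0, 0]],
                                ["s1", "s2"], list("abcd"))
        sm, _ = smooth_alterations(mat, mat, net)
        # rescaling keeps the seeded sample strictly above the empty one
        assert (sm.values.loc["s1"] > 0).all()
        assert (sm.values.loc["s2"] == 0).all()

    def test_identical_rows_stay_identical(self):
        net = net_from([("a", "b"), ("b", "c")])
        mat = self.binary_frame([[1, 0, 1], [1, 0, 1], [0, 1, 0]],
                                ["s1", "s2", "s3"], list("abc"))
        sm, _ = smooth_alterations(mat, mat, net)
        pd.testing.assert_series_equal(sm.values.loc["s1"],
                                       sm.values.loc["s2"], check_names=False)

    def test_output_bounded_in_unit_interval(self, rng):
        net = net_from([(f"g{i}", f"g{i + 1}") for i in range(9)])
        vals = (rng.random((6, 10)) < 0.3).astype(int)
        mat = self.binary_frame(vals, [f"s{i}" for i in range(6)],
                                [f"g{i}" for i in range(10)])
        sm, _ = smooth_alterations(mat, mat, net)
        arr = sm.values.to_numpy()
        assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_non_binary_matrix_rejected(self):
        net = net_from([("a", "b")])
        mat = pd.DataFrame([[0.5, 0.0]], index=["s1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="binary"):
            smooth_alterations(mat, mat, net)

    def test_sample_intersection_taken(self):
        net = net_from([("a", "b")])
        mut = self.binary_frame([[1, 0], [0, 1]], ["s1", "s2"], ["a", "b"])
        cnv = self.binary_frame([[1, 1]], ["s1"], ["a", "b"])
        sm_mut, sm_cnv = smooth_alterations(mut, cnv, net)
        assert list(sm_mut.values.index) == ["s1"]
        assert list(sm_cnv.values.index) == ["s1"]
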