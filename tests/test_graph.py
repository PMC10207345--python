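"""Adjacency graphs, ICAR Laplacians, and BYM2 scaling constants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stgap
from stgap.graph import (
    build_graph,
    bym2_scaling_factor,
    constrained_icar_covariance,
    icar_precision,
    read_edge_list,
    write_edge_list,
)


class TestBuildGraph:
    def test_path_graph(self):
        g = build_graph(["A", "B", "C"], [("A", "B"), ("B", "C")])
        assert g.n_nodes == 3 and g.n_edges == 2
        assert g.edges == ((0, 1), (1, 2))

    def test_reversed_duplicate_edges_collapse(self):
        g = build_graph(["A", "B"], [("A", "B"), ("B", "A")])
        assert g.n_edges == 1

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            build_graph(["A"], [("A", "A")])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not a known node"):
            build_graph(["A", "B"], [("A", "Z")])

    def test_duplicate_node_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            build_graph(["A", "A"], [])

    def test_edge_list_roundtrip(self, tmp_path):
        g = build_graph(["A", "B", "C", "D"], [("A", "B"), ("C", "D")])
        path = tmp_path / "edges.txt"
        write_edge_list(g, path)
        g2 = read_edge_list(path, ["A", "B", "C", "D"])
        assert g2 == g

    def test_edge_list_allows_isolated_nodes(self, tmp_path):
        path = tmp_path / "edges.txt"
        path.write_text("# comment\nA\tB\n")
        g = read_edge_list(path, ["A", "B", "Island"])
        assert g.n_nodes == 3 and g.n_edges == 1
        assert g.degrees()[2] == 0


class TestIcarPrecision:
    def test_path_graph_laplacian(self, path3):
        icar = icar_precision(path3)
        expected = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float)
        np.testing.assert_array_equal(icar.Q.toarray(), expected)

    def test_complete_graph_laplacian_and_rank(self, k3):
        icar = icar_precision(k3)
        expected = np.array([[2, -1, -1], [-1, 2, -1], [-1, -1, 2]], dtype=float)
        np.testing.assert_array_equal(icar.Q.toarray(), expected)
        assert np.linalg.matrix_rank(icar.Q.toarray()) == 2

    def test_components_and_rank_with_isolates(self):
        g = build_graph(["A", "B", "C", "D"], [("C", "D")])
        icar = icar_precision(g)
        assert icar.n_components == 3
        assert np.linalg.matrix_rank(icar.Q.toarray()) == 1

    def test_k3_scaling_factor_exact(self, k3):
        # Q = 3I - J on the sum-to-zero subspace; pseudo-inverse diagonal 2/9
        icar = icar_precision(k3)
        assert icar.scaling_factor == pytest.approx([2.0 / 9.0], abs=1e-12)

    def test_isolated_node_scaling_is_one(self):
        g = build_graph(["A", "B", "C"], [("A", "B")])
        icar = icar_precision(g)
        kappa = icar.node_scaling()
        assert kappa[2] == 1.0

    def test_path_scaling_matches_dense_pinv(self, path3):
        icar = icar_precision(path3)
        pinv = np.linalg.pinv(icar.Q.toarray(), hermitian=True)
        expected = np.exp(np.mean(np.log(np.diag(pinv))))
        assert bym2_scaling_factor(icar)[0] == pytest.approx(expected, rel=1e-12)


def _random_graph(rng, n):
    ids = [f"N{i}" for i in range(n)]
    n_edges = int(rng.integers(1, max(2, n * 2)))
    edges = []
    for _ in range(n_edges):
        i, j = rng.choice(n, size=2, replace=False)
        edges.append((ids[i], ids[j]))
    return build_graph(ids, edges)


class TestRandomGraphInvariants:
    def test_scaling_matches_dense_oracle_on_random_graphs(self):
        """Geometric-mean marginal variance vs. a dense pseudo-inverse oracle."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 31))
            g = _random_graph(rng, n)
            icar = icar_precision(g)
            Q = icar.Q.toarray()
            labels = icar.component_labels
            for c in range(icar.n_components):
                idx = np.flatnonzero(labels == c)
                if idx.size < 2:
                    assert icar.scaling_factor[c] == 1.0
                    continue
                pinv = np.linalg.pinv(Q[np.ix_(idx, idx)], hermitian=True)
                oracle = np.exp(np.mean(np.log(np.diag(pinv))))
                assert icar.scaling_factor[c] == pytest.approx(oracle, rel=1e-8)

    def test_laplacian_row_sums_and_rank(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(2, 51))
            g = _random_graph(rng, n)
            icar = icar_precision(g)
            Q = icar.Q.toarray()
            np.testing.assert_allclose(Q @ np.ones(n), 0.0, atol=1e-12)
            np.testing.assert_array_equal(Q, Q.T)
            evals = np.linalg.eigvalsh(Q)
            n_null = int((np.abs(evals) < 1e-9).sum())
            assert n_null == icar.n_components

    def test_scaled_covariance_has_unit_geometric_mean_variance(self):
        """Dividing the structured covariance by kappa normalizes its scale."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(4, 31))
            g = _random_graph(rng, n)
            icar = icar_precision(g)
            cov = constrained_icar_covariance(icar, scaled=True)
            labels = icar.component_labels
            for c in range(icar.n_components):
                idx = np.flatnonzero(labels == c)
                if idx.size < 2:
                    continue
                gm = np.exp(np.mean(np.log(np.diag(cov)[idx])))
                assert gm == pytest.approx(1.0, abs=1e-8)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=12),
    raw_edges=st.lists(
        st.tuples(st.integers(0, 11), st.integers(0, 11)), max_size=20
    ),
)
def test_build_graph_properties(n, raw_edges):
    """Edge sets are deduplicated, symmetric, self-loop-free index pairs."""
    ids = [f"N{i}" for i in range(n)]
    edges = [(ids[a % n], ids[b % n]) for a, b in raw_edges if a % n != b % n]
    g = build_graph(ids, edges)
    assert all(i < j for i, j in g.edges)
    assert len(set(g.edges)) == g.n_edges
    deg = g.degrees()
    assert deg.sum() == 2 * g.n_edges
    Q = icar_precision(g).Q.toarray()
    np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    assert np.all(np.diag(Q) == deg)
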