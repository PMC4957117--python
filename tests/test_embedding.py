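import networkx as nx
import numpy as np
import pytest

from labne.embedding import (
    build_laplacian,
    angular_coordinates,
    labne_embed,
    radial_coordinates,
    solve_generalized_eigenproblem,
)
from labne.geometry import angular_separation, distance_matrix


class TestLaplacian:
    def test_path_graph(self):
        G = nx.path_graph(["a", "b", "c"])
        L, D = build_laplacian(G)
        np.testing.assert_array_equal(D.diagonal(), [1, 2, 1])
        np.testing.assert_allclose(np.asarray(L.sum(axis=1)).ravel(), 0.0)
        assert (L != L.T).nnz == 0

    def test_triangle_entrywise(self):
        G = nx.complete_graph(3)
        L, _ = build_laplacian(G)
        expected = 2 * np.eye(3) - (np.ones((3, 3)) - np.eye(3))
        np.testing.assert_array_equal(L.toarray(), expected)

    def test_disconnected_rejected(self):
        G = nx.Graph([(1, 2), (3, 4)])
        with pytest.raises(ValueError, match="single-component"):
            build_laplacian(G)

    def test_tiny_graph_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            build_laplacian(nx.Graph([(1, 2)]))


class TestGeneralizedEigenproblem:
    def test_zero_mode_with_constant_eigenvector(self):
        G = nx.erdos_renyi_graph(40, 0.3, seed=4)
        assert nx.is_connected(G)
        L, D = build_laplacian(G)
        vals, vecs = solve_generalized_eigenproblem(L, D)
        assert abs(vals[0]) < 1e-8
        v0 = vecs[:, 0]
        assert np.ptp(v0) == pytest.approx(0.0, abs=1e-6 * np.abs(v0).max())

    def test_complete_graph_closed_form(self):
        # L = nI - J, D = (n-1)I: nonzero generalized eigenvalues n/(n-1)
        L, D = build_laplacian(nx.complete_graph(5))
        vals, _ = solve_generalized_eigenproblem(L, D)
        np.testing.assert_allclose(vals[1:], 5 / 4, atol=1e-8)

    @pytest.mark.parametrize("n", [6, 9])
    def test_cycle_closed_form(self, n):
        # circulant: generalized eigenvalues 1 - cos(2 pi j / n), D = 2I
        L, D = build_laplacian(nx.cycle_graph(n))
        vals, _ = solve_generalized_eigenproblem(L, D)
        analytic = np.sort(1 - np.cos(2 * np.pi * np.arange(n) / n))[:3]
        np.testing.assert_allclose(vals, analytic, atol=1e-8)

    def test_large_cycle_sparse_path(self):
        # n = 600 exercises the shift-invert ARPACK branch
        n = 600
        L, D = build_laplacian(nx.cycle_graph(n))
        vals, vecs = solve_generalized_eigenproblem(L, D)
        analytic = np.sort(1 - np.cos(2 * np.pi * np.arange(n) / n))[:3]
        np.testing.assert_allclose(vals, analytic, atol=1e-8)
        self._assert_d_orthonormal(vecs, D)

    @staticmethod
    def _assert_d_orthonormal(vecs, D):
        gram = vecs.T @ (D @ vecs)
        np.testing.assert_allclose(gram, np.eye(vecs.shape[1]), atol=1e-8)

    def test_d_orthonormality(self):
        G = nx.random_regular_graph(4, 30, seed=2)
        L, D = build_laplacian(G)
        _, vecs = solve_generalized_eigenproblem(L, D)
        self._assert_d_orthonormal(vecs, D)

    def test_invalid_k_rejected(self):
        L, D = build_laplacian(nx.complete_graph(4))
        with pytest.raises(ValueError):
            solve_generalized_eigenproblem(L, D, k=4)


class TestAngularCoordinates:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((1, 0), 0.0),
            ((0, 1), np.pi / 2),
            ((-1, 0), np.pi),
            ((0, -1), 3 * np.pi / 2),
            ((1, 1), np.pi / 4),
        ],
    )
    def test_quadrant_aware_axis_cases(self, row, expected):
        theta = angular_coordinates(np.array([row], dtype=float))
        assert theta[0] == pytest.approx(expected)

    def test_zero_row_warned_and_zeroed(self, caplog):
        with caplog.at_level("WARNING"):
            theta = angular_coordinates(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert theta[0] == 0.0
        assert "y1 = y2 = 0" in caplog.text


class TestRadialCoordinates:
    def test_endpoints_exact(self):
        G = nx.barabasi_albert_graph(100, 3, seed=1)
        gamma = 2.5
        beta = 1 / (gamma - 1)
        r, rank = radial_coordinates(G, gamma)
        N = 100
        assert r[rank == 1][0] == 2 * (1 - beta) * np.log(N)
        assert r[rank == N][0] == 2 * np.log(N)

    def test_direct_evaluation_gamma_three(self):
        # gamma = 3 -> beta = 1/2; N = 100, rank 10 -> ln 10 + ln 100
        G = nx.path_graph(100)
        r, rank = radial_coordinates(G, 3.0)
        assert r[rank == 10][0] == pytest.approx(np.log(1000))

    def test_monotone_in_rank(self):
        G = nx.barabasi_albert_graph(60, 2, seed=3)
        r, rank = radial_coordinates(G, 2.3)
        order = np.argsort(rank)
        assert np.all(np.diff(r[order]) >= 0)

    def test_rank_ties_broken_by_label(self):
        G = nx.cycle_graph([3, 1, 2, 0])  # all degree 2
        _, rank = radial_coordinates(G, 2.5, nodelist=[3, 1, 2, 0])
        assert dict(zip([3, 1, 2, 0], rank)) == {0: 1, 1: 2, 2: 3, 3: 4}

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            radial_coordinates(nx.path_graph(5), 1.0)


class TestLabneEmbed:
    def test_radial_span(self, small_ps_net):
        params, graph, _ = small_ps_net
        res = labne_embed(graph, gamma=params.gamma)
        beta = 1 / (params.gamma - 1)
        N = graph.number_of_nodes()
        assert res.coords.r.min() == pytest.approx(2 * (1 - beta) * np.log(N))
        assert res.coords.r.max() == pytest.approx(2 * np.log(N))
        assert abs(res.eigenvalues[0]) < 1e-8

    def test_linked_pairs_are_angularly_closer(self, small_ps_net):
        params, graph, _ = small_ps_net
        res = labne_embed(graph, gamma=params.gamma)
        theta = {v: t for v, t in zip(res.coords.node_ids, res.coords.theta)}
        adj_sep = np.mean([angular_separation(theta[u], theta[v])
                           for u, v in graph.edges])
        rng = np.random.default_rng(0)
        nodes = list(graph.nodes)
        non_adj = []
        while len(non_adj) < graph.number_of_edges():
            u, v = rng.choice(nodes, 2, replace=False)
            if not graph.has_edge(u, v):
                non_adj.append(angular_separation(theta[u], theta[v]))
        assert adj_sep < np.mean(non_adj)

    def test_permutation_equivariance(self, small_ps_net):
        # relabelling the graph must not change the geometry: per-node
        # angular separations are preserved (angles are defined up to a
        # global rotation/reflection) and the multiset of radii is
        # identical.  Individual radii may swap among degree-tied nodes,
        # whose ranks are broken by label.
        _, graph, _ = small_ps_net
        res = labne_embed(graph, gamma=2.5)
        rng = np.random.default_rng(1)
        nodes = list(graph.nodes)
        relabel = dict(zip(nodes, rng.permutation(nodes)))
        res_p = labne_embed(nx.relabel_nodes(graph, relabel), gamma=2.5)
        theta0 = {v: t for v, t in zip(res.coords.node_ids, res.coords.theta)}
        theta1 = {v: t for v, t in zip(res_p.coords.node_ids, res_p.coords.theta)}
        for _ in range(200):
            u, v = rng.choice(nodes, 2, replace=False)
            s0 = angular_separation(theta0[u], theta0[v])
            s1 = angular_separation(theta1[relabel[u]], theta1[relabel[v]])
            assert s0 == pytest.approx(s1, abs=1e-6)
        np.testing.assert_allclose(
            np.sort(res.coords.r), np.sort(res_p.coords.r), atol=1e-12
        )

    def test_sign_flip_leaves_distances_unchanged(self, small_ps_net):
        from labne.geometry import PolarCoords

        params, graph, _ = small_ps_net
        res = labne_embed(graph, gamma=params.gamma)
        flipped = angular_coordinates(res.Y * np.array([-1.0, 1.0]))
        c2 = PolarCoords(res.coords.node_ids, res.coords.r, flipped)
        np.testing.assert_allclose(
            np.sort(distance_matrix(res.coords)), np.sort(distance_matrix(c2)),
            atol=1e-8,
        )

    def test_auto_gamma(self, small_ps_net):
        params, graph, _ = small_ps_net
        res = labne_embed(graph, gamma="auto")
        assert 2.01 <= res.gamma_used <= 3.5
        assert res.gamma_used == pytest.approx(params.gamma, abs=0.5)

    def test_bad_gamma_rejected(self, small_ps_net):
        with pytest.raises(ValueError):
            labne_embed(small_ps_net[1], gamma=0.9)
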