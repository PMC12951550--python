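from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from sheafscreen.clique_filtration import SimplicialComplex, build_clique_complex
from sheafscreen.network_io import DEGRecord, InteractionEdge, build_labeled_network
from sheafscreen.sheaf_spectra import (
    SheafAssignment,
    coboundary_matrix,
    constant_sheaf,
    default_sheaf,
    persistent_sheaf_laplacian,
    restriction_scalar,
    sheaf_laplacian,
    spectrum,
    summarize_spectrum,
)

from conftest import random_clique_complex
from oracles import betti_numbers


def _edge_complex():
    return SimplicialComplex([("a",), ("b",), ("a", "b")], max_dim=1)


def _edge_sheaf(qa, qb, r):
    return SheafAssignment(q={"a": qa, "b": qb}, F=lambda s: 1.0 if len(s) == 1 else r)


class TestRestrictionScalar:
    def test_vertex_to_edge_is_qj_over_r(self):
        sheaf = _edge_sheaf(qa=3.0, qb=5.0, r=0.5)
        assert restriction_scalar(("a",), ("a", "b"), sheaf) == pytest.approx(5.0 / 0.5)
        assert restriction_scalar(("b",), ("a", "b"), sheaf) == pytest.approx(3.0 / 0.5)

    def test_identity_on_equal_simplices(self):
        sheaf = _edge_sheaf(1.0, 2.0, 0.3)
        assert restriction_scalar(("a", "b"), ("a", "b"), sheaf) == 1.0

    def test_vertex_to_triangle_product(self):
        # q1 = 2, q2 = 3, F == 1 -> product 6
        sheaf = SheafAssignment(q={"v0": 1.0, "v1": 2.0, "v2": 3.0}, F=lambda s: 1.0)
        assert restriction_scalar(("v0",), ("v0", "v1", "v2"), sheaf) == pytest.approx(6.0)

    def test_non_face_errors(self):
        sheaf = _edge_sheaf(1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            restriction_scalar(("c",), ("a", "b"), sheaf)

    def test_composition_along_faces(self):
        # restriction(tau->sigma) = restriction(tau->rho) * restriction(rho->sigma)
        rng = np.random.default_rng(0)
        q = {v: float(rng.uniform(0.5, 3)) for v in ("a", "b", "c")}
        weights = {1: 1.0, 2: 0.7, 3: 0.4}
        sheaf = SheafAssignment(q=q, F=lambda s: weights[len(s)])
        tau, rho, sigma = ("a",), ("a", "b"), ("a", "b", "c")
        assert restriction_scalar(tau, sigma, sheaf) == pytest.approx(
            restriction_scalar(tau, rho, sheaf) * restriction_scalar(rho, sigma, sheaf)
        )


class TestDefaultSheaf:
    def test_edge_length_from_score(self, path_network):
        K = build_clique_complex(path_network, 500, 2)
        sheaf = default_sheaf(path_network, K)
        assert sheaf.weight(("A", "B")) == pytest.approx(0.4)  # score 600
        assert sheaf.weight(("B", "C")) == pytest.approx(0.2)  # score 800

    def test_score_1000_floored(self):
        net = build_labeled_network(
            [DEGRecord("a", 1.0, 0.01), DEGRecord("b", 1.0, 0.01)],
            [InteractionEdge("a", "b", 1000)],
        )
        K = build_clique_complex(net, 500, 1)
        sheaf = default_sheaf(net, K)
        assert sheaf.weight(("a", "b")) == pytest.approx(1e-3)

    def test_triangle_mean_edge_length(self):
        net = build_labeled_network(
            [DEGRecord(g, 1.0, 0.01) for g in "abc"],
            [
                InteractionEdge("a", "b", 500),
                InteractionEdge("a", "c", 600),
                InteractionEdge("b", "c", 700),
            ],
        )
        K = build_clique_complex(net, 400, 2)
        sheaf = default_sheaf(net, K)
        assert sheaf.weight(("a", "b", "c")) == pytest.approx(np.mean([0.5, 0.4, 0.3]))

    def test_vertex_weight_is_one(self, triangle_network):
        K = build_clique_complex(triangle_network, 700, 2)
        sheaf = default_sheaf(triangle_network, K)
        assert sheaf.weight(("A",)) == 1.0

    def test_q_from_network_labels(self, triangle_network):
        K = build_clique_complex(triangle_network, 700, 2)
        sheaf = default_sheaf(triangle_network, K)
        assert sheaf.q == triangle_network.q


class TestCoboundary:
    def test_single_edge_constant(self):
        D = coboundary_matrix(_edge_complex(), _edge_sheaf(1, 1, 1), 0)
        np.testing.assert_array_equal(D, [[-1.0, 1.0]])

    def test_global_section_in_kernel(self):
        qa, qb, r = 2.0, 3.0, 0.6
        D = coboundary_matrix(_edge_complex(), _edge_sheaf(qa, qb, r), 0)
        np.testing.assert_allclose(D, [[-qb / r, qa / r]])
        section = np.array([qa, qb])
        assert abs(D @ section) < 1e-12

    def test_chain_complex_identity_triangle(self, triangle_network):
        K = build_clique_complex(triangle_network, 700, 2)
        sheaf = constant_sheaf(K)
        d0 = coboundary_matrix(K, sheaf, 0)
        d1 = coboundary_matrix(K, sheaf, 1)
        np.testing.assert_array_equal(d1 @ d0, np.zeros((1, 3)))

    def test_row_nonzero_count(self):
        rng = np.random.default_rng(4)
        K = random_clique_complex(rng, max_nodes=8)
        sheaf = constant_sheaf(K)
        for degree in (0, 1):
            D = coboundary_matrix(K, sheaf, degree)
            if D.size:
                assert (np.count_nonzero(D, axis=1) == degree + 2).all()


class TestSheafLaplacian:
    def test_single_edge_constant(self):
        L = sheaf_laplacian(_edge_complex(), _edge_sheaf(1, 1, 1), 0)
        np.testing.assert_array_equal(L, [[1, -1], [-1, 1]])
        np.testing.assert_allclose(spectrum(L), [0, 2], atol=1e-12)

    def test_single_edge_q12(self):
        L = sheaf_laplacian(_edge_complex(), _edge_sheaf(1, 2, 1), 0)
        np.testing.assert_allclose(L, [[4, -2], [-2, 1]])
        np.testing.assert_allclose(spectrum(L), [0, 5], atol=1e-12)

    def test_unfilled_triangle_spectrum(self):
        K = SimplicialComplex(
            [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c")], max_dim=1
        )
        L = sheaf_laplacian(K, constant_sheaf(K), 0)
        np.testing.assert_allclose(spectrum(L), [0, 3, 3], atol=1e-12)

    def test_constant_sheaf_is_graph_laplacian(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            K = random_clique_complex(rng, max_nodes=12)
            L = sheaf_laplacian(K, constant_sheaf(K), 0)
            g = nx.Graph()
            g.add_nodes_from(K.vertices)
            g.add_edges_from(K.simplices(1))
            expected = nx.laplacian_matrix(g, nodelist=K.vertices).toarray()
            np.testing.assert_allclose(L, expected, atol=1e-12)

    def test_psd_under_random_sheaf(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            K = random_clique_complex(rng, max_nodes=8)
            q = {v: float(rng.uniform(0.2, 4)) for v in K.vertices}
            weights = {s: float(rng.uniform(0.1, 2)) for s in K}
            sheaf = SheafAssignment(q=q, F=lambda s: weights[s] if len(s) > 1 else 1.0)
            for degree in (0, 1):
                L = sheaf_laplacian(K, sheaf, degree)
                if L.size:
                    assert np.allclose(L, L.T)
                    norm = np.linalg.norm(L)
                    assert spectrum(L).min() >= -1e-10 * max(1.0, norm)

    def test_empty_degree_zero_matrix(self):
        K = SimplicialComplex([("a",), ("b",)], max_dim=2)
        assert sheaf_laplacian(K, constant_sheaf(K), 1).shape == (0, 0)

    def test_nullity_matches_betti(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            K = random_clique_complex(rng, max_nodes=9)
            betti = betti_numbers(list(K), K.max_dim)
            sheaf = constant_sheaf(K)
            for degree in (0, 1):
                L = sheaf_laplacian(K, sheaf, degree)
                if L.size == 0:
                    assert betti[degree] == 0
                    continue
                eigs = spectrum(L)
                nullity = int((eigs <= 1e-8 * max(1.0, eigs.max())).sum())
                assert nullity == betti[degree]


class TestPersistentLaplacian:
    def test_vertices_then_edge(self):
        K_small = SimplicialComplex([("a",), ("b",)], max_dim=1)
        K_big = _edge_complex()
        sheaf = _edge_sheaf(1, 1, 1)
        L = persistent_sheaf_laplacian(K_small, K_big, sheaf, 0)
        np.testing.assert_allclose(L, [[1, -1], [-1, 1]])
        eigs = spectrum(L)
        assert int((eigs <= 1e-10).sum()) == 1  # persistent beta_0 = 1

    def test_equal_pair_reduces_to_plain_laplacian(self, triangle_network):
        K = build_clique_complex(triangle_network, 700, 2)
        sheaf = default_sheaf(triangle_network, K)
        for degree in (0, 1):
            np.testing.assert_allclose(
                persistent_sheaf_laplacian(K, K, sheaf, degree),
                sheaf_laplacian(K, sheaf, degree),
                atol=1e-12,
            )

    def test_triangle_boundary_into_filled(self):
        K_small = SimplicialComplex(
            [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c")], max_dim=2
        )
        K_big = SimplicialComplex(
            [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c"), ("a", "b", "c")],
            max_dim=2,
        )
        sheaf = SheafAssignment(q={v: 1.0 for v in "abc"}, F=lambda s: 1.0)
        L = persistent_sheaf_laplacian(K_small, K_big, sheaf, 1)
        eigs = spectrum(L)
        assert int((eigs <= 1e-8 * max(1.0, eigs.max())).sum()) == 0  # 1-cycle dies

    def test_not_subcomplex_errors(self):
        K_small = SimplicialComplex([("a",), ("c",)], max_dim=1)
        with pytest.raises(ValueError):
            persistent_sheaf_laplacian(K_small, _edge_complex(), _edge_sheaf(1, 1, 1), 0)


class TestSummarizeSpectrum:
    def test_zero_two(self):
        s = summarize_spectrum(np.array([0.0, 2.0]))
        assert (s.min, s.mean, s.max, s.std, s.sum, s.n_zero) == (0, 1, 2, 1, 2, 1)

    def test_constant_positive(self):
        s = summarize_spectrum(np.array([3.0, 3.0, 3.0]))
        assert s.std == 0 and s.n_zero == 0

    def test_empty_convention(self):
        s = summarize_spectrum(np.array([]))
        assert s.as_array().tolist() == [0, 0, 0, 0, 0, 0]

    def test_sum_equals_trace(self):
        rng = np.random.default_rng(3)
        K = random_clique_complex(rng, max_nodes=10)
        L = sheaf_laplacian(K, constant_sheaf(K), 0)
        s = summarize_spectrum(spectrum(L))
        assert s.sum == pytest.approx(np.trace(L))

    def test_population_std(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        s = summarize_spectrum(vals)
        assert s.std == pytest.approx(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
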