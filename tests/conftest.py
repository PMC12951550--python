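from __future__ import annotations

import numpy as np
import pytest

from sheafscreen.clique_filtration import SimplicialComplex, _clique_complex_from_graph
from sheafscreen.network_io import DEGRecord, InteractionEdge, build_labeled_network

import networkx as nx


@pytest.fixture
def triangle_network():
    """Three genes, all pairwise edges at score 900 (a filled triangle)."""
    degs = [
        DEGRecord("A", 1.5, 0.01),
        DEGRecord("B", 0.8, 0.02),
        DEGRecord("C", 2.0, 0.001),
    ]
    edges = [
        InteractionEdge("A", "B", 900),
        InteractionEdge("B", "C", 900),
        InteractionEdge("A", "C", 900),
    ]
    return build_labeled_network(degs, edges)


@pytest.fixture
def path_network():
    """A - B - C path, scores 600 and 800."""
    degs = [
        DEGRecord("A", 1.0, 0.01),
        DEGRecord("B", 2.0, 0.01),
        DEGRecord("C", 0.5, 0.01),
    ]
    edges = [InteractionEdge("A", "B", 600), InteractionEdge("B", "C", 800)]
    return build_labeled_network(degs, edges)


def random_clique_complex(rng: np.random.Generator, max_nodes: int = 10,
                          edge_p: float = 0.35, max_dim: int = 2) -> SimplicialComplex:
    """Clique complex of a G(n, p) graph with string vertex labels."""
    n = int(rng.integers(3, max_nodes + 1))
    g = nx.gnp_random_graph(n, edge_p, seed=int(rng.integers(0, 2**31)))
    g = nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes})
    return _clique_complex_from_graph(g, max_dim)
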