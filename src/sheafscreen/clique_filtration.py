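"""Oriented clique complexes over the confidence filtration.

Simplices are tuples of gene symbols in ascending lexicographic order; that
order fixes the orientation (the incidence sign of dropping the vertex at
position ``i`` is ``(-1)**i``).  The filtration is over the minimum edge
confidence: raising the threshold removes edges and the cliques they span,
so the complex at a higher threshold is nested inside the one at a lower
threshold.  Vertices never die — thresholds gate edges only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from sheafscreen.network_io import LabeledNetwork

#: Confidence thresholds as printed, loosest first.
DEFAULT_THRESHOLDS = (250, 400, 550, 700)

Simplex = tuple[str, ...]


@dataclass(frozen=True)
class FiltrationSpec:
    """Thresholds (strictly increasing, each in (0, 1000]) and max dimension."""

    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    max_dim: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(self.thresholds))
        if not self.thresholds:
            raise ValueError("at least one threshold required")
        if any(not 0 < t <= 1000 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1000]")
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.max_dim not in (1, 2, 3):
            raise ValueError("max_dim must be 1, 2 or 3")


class SimplicialComplex:
    """Simplices grouped by dimension with deterministic per-dimension ordinals.

    Closed under faces by construction; ordinals are the lexicographic rank of
    the vertex tuple within its dimension.
    """

    def __init__(self, simplices: Iterable[Simplex], max_dim: int):
        self.max_dim = max_dim
        by_dim: dict[int, set[Simplex]] = {d: set() for d in range(max_dim + 1)}
        for s in simplices:
            s = tuple(s)
            if len(s) != len(set(s)):
                raise ValueError(f"repeated vertex in simplex {s}")
            if list(s) != sorted(s):
                raise ValueError(f"simplex vertices not ascending: {s}")
            if len(s) - 1 > max_dim:
                raise ValueError(f"simplex {s} exceeds max_dim {max_dim}")
            by_dim[len(s) - 1].add(s)
        self._simplices: dict[int, list[Simplex]] = {
            d: sorted(by_dim[d]) for d in range(max_dim + 1)
        }
        self._index: dict[int, dict[Simplex, int]] = {
            d: {s: i for i, s in enumerate(self._simplices[d])}
            for d in range(max_dim + 1)
        }
        self._check_closure()

    def _check_closure(self) -> None:
        for d in range(1, self.max_dim + 1):
            for s in self._simplices[d]:
                for f in faces(s):
                    if f not in self._index[d - 1]:
                        raise ValueError(f"complex not closed: face {f} of {s} missing")

    # -- queries ---------------------------------------------------------

    def simplices(self, dim: int) -> list[Simplex]:
        """Simplices of one dimension, lexicographic order."""
        return self._simplices.get(dim, [])

    def n_simplices(self, dim: int) -> int:
        return len(self._simplices.get(dim, ()))

    def ordinal(self, simplex: Simplex) -> int:
        return self._index[len(simplex) - 1][simplex]

    def __contains__(self, simplex: Simplex) -> bool:
        d = len(simplex) - 1
        return d in self._index and tuple(simplex) in self._index[d]

    def __iter__(self) -> Iterator[Simplex]:
        for d in range(self.max_dim + 1):
            yield from self._simplices[d]

    def __len__(self) -> int:
        return sum(len(v) for v in self._simplices.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimplicialComplex):
            return NotImplemented
        return self._simplices == other._simplices

    def __repr__(self) -> str:
        counts = ", ".join(f"n{d}={self.n_simplices(d)}" for d in range(self.max_dim + 1))
        return f"SimplicialComplex({counts})"

    def is_subcomplex_of(self, other: "SimplicialComplex") -> bool:
        return all(s in other for s in self)

    @property
    def vertices(self) -> list[str]:
        return [s[0] for s in self._simplices[0]]

    def export_text(self, path: str | Path) -> None:
        """One simplex per line, tab-separated vertex symbols (debug/oracle)."""
        with open(path, "w") as fh:
            for s in self:
                fh.write("\t".join(s) + "\n")


def faces(simplex: Simplex) -> Iterator[Simplex]:
    """Codimension-1 faces, in order of the dropped-vertex position."""
    for i in range(len(simplex)):
        yield simplex[:i] + simplex[i + 1 :]


def build_clique_complex(
    network: LabeledNetwork, min_score: int, max_dim: int = 2
) -> SimplicialComplex:
    """Clique complex of the subgraph with edge score >= ``min_score``.

    All genes appear as 0-simplices regardless of threshold.
    """
    graph = nx.Graph()
    graph.add_nodes_from(network.genes)
    graph.add_edges_from(e.pair for e in network.edges if e.score >= min_score)
    return _clique_complex_from_graph(graph, max_dim)


def _clique_complex_from_graph(graph: nx.Graph, max_dim: int) -> SimplicialComplex:
    simplices: list[Simplex] = [(v,) for v in graph.nodes]
    for clique in nx.enumerate_all_cliques(graph):
        if len(clique) > max_dim + 1:
            break  # enumerate_all_cliques yields by increasing size
        if len(clique) >= 2:
            simplices.append(tuple(sorted(clique)))
    return SimplicialComplex(simplices, max_dim)


def build_confidence_filtration(
    network: LabeledNetwork, spec: FiltrationSpec = FiltrationSpec()
) -> list[SimplicialComplex]:
    """One clique complex per threshold, in the order of ``spec.thresholds``
    (loosest first); complexes are nested: higher threshold ⊆ lower."""
    return [
        build_clique_complex(network, min_score=t, max_dim=spec.max_dim)
        for t in spec.thresholds
    ]


def remove_vertex_star(complex_: SimplicialComplex, gene: str) -> SimplicialComplex:
    """Delete a vertex and every simplex containing it."""
    if (gene,) not in complex_:
        raise KeyError(f"gene {gene!r} is not a vertex of the complex")
    return SimplicialComplex(
        (s for s in complex_ if gene not in s), complex_.max_dim
    )
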