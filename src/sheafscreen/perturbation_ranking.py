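"""Topological perturbation scores and the intersected top-k gene set.

For each filtration scale, a complex is summarized by a 12-entry feature
vector (six statistics of the L0 spectrum followed by six of L1).  A gene's
score at a scale is the order-1 Wasserstein distance between the feature
vector of the complex and that of the complex with the gene's vertex star
deleted.  Genes are ranked per scale by descending distance; the final set
is the intersection of the per-scale top-k prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from sheafscreen.clique_filtration import SimplicialComplex, remove_vertex_star
from sheafscreen.network_io import LabeledNetwork
from sheafscreen.sheaf_spectra import (
    SheafAssignment,
    default_sheaf,
    sheaf_laplacian,
    spectrum,
    summarize_spectrum,
)

SheafFactory = Callable[[LabeledNetwork, SimplicialComplex], SheafAssignment]
DistanceMode = Literal["concatenated", "per_laplacian"]


@dataclass(frozen=True)
class FeatureVector:
    """(6 stats of L0 spectrum, 6 stats of L1 spectrum) at one scale."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 12:
            raise ValueError(f"feature vector must have 12 entries, got {len(self.values)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector entries must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(self.values)

    @property
    def l0_block(self) -> tuple[float, ...]:
        return self.values[:6]

    @property
    def l1_block(self) -> tuple[float, ...]:
        return self.values[6:]


@dataclass(frozen=True)
class PerturbationScore:
    gene: str
    scale: int
    distance: float

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be nonnegative")


@dataclass
class RankingResult:
    """Per-scale descending-distance rankings and their top-k intersection."""

    per_scale: dict[int, list[str]]
    intersected: set[str]
    top_k: int
    frequencies: dict[str, int] = field(default_factory=dict)


def feature_vector(
    complex_: SimplicialComplex, sheaf: SheafAssignment, zero_tol: float | None = None
) -> FeatureVector:
    """Concatenated L0/L1 spectral summaries; empty degrees give zero blocks."""
    kwargs = {} if zero_tol is None else {"zero_tol": zero_tol}
    blocks = []
    for degree in (0, 1):
        eigs = spectrum(sheaf_laplacian(complex_, sheaf, degree))
        blocks.extend(summarize_spectrum(eigs, **kwargs).as_array())
    return FeatureVector(values=tuple(float(v) for v in blocks))


def wasserstein_1d(f: Sequence[float] | FeatureVector, g: Sequence[float] | FeatureVector) -> float:
    """Order-1 Wasserstein distance between two equal-length value lists viewed
    as equal-weight empirical distributions: the mean absolute difference of
    the sorted lists."""
    fa = f.as_array() if isinstance(f, FeatureVector) else np.asarray(f, dtype=float)
    ga = g.as_array() if isinstance(g, FeatureVector) else np.asarray(g, dtype=float)
    if fa.shape != ga.shape:
        raise ValueError(f"length mismatch: {fa.shape} vs {ga.shape}")
    if fa.size == 0:
        return 0.0
    return float(np.mean(np.abs(np.sort(fa) - np.sort(ga))))


def _distance(f: FeatureVector, g: FeatureVector, mode: DistanceMode) -> float:
    if mode == "concatenated":
        return wasserstein_1d(f, g)
    if mode == "per_laplacian":
        return wasserstein_1d(f.l0_block, g.l0_block) + wasserstein_1d(
            f.l1_block, g.l1_block
        )
    raise ValueError(f"unknown distance mode {mode!r}")


_ZERO_FEATURES = FeatureVector(values=(0.0,) * 12)


def score_gene(
    network: LabeledNetwork,
    complexes: Sequence[SimplicialComplex],
    scales: Sequence[int],
    gene: str,
    sheaf_factory: SheafFactory = default_sheaf,
    mode: DistanceMode = "concatenated",
    baseline: Sequence[FeatureVector] | None = None,
) -> list[PerturbationScore]:
    """One perturbation score per filtration scale for a single gene.

    ``baseline`` lets callers reuse the unperturbed feature vectors across
    genes; when omitted they are recomputed here.
    """
    if gene not in network.q:
        raise KeyError(f"gene {gene!r} not in network")
    if len(complexes) != len(scales):
        raise ValueError("complexes and scales must align")
    if baseline is None:
        baseline = [feature_vector(K, sheaf_factory(network, K)) for K in complexes]

    scores = []
    for K, scale, f in zip(complexes, scales, baseline):
        K_pert = remove_vertex_star(K, gene)
        if len(K_pert) == 0:
            f_hat = _ZERO_FEATURES
        else:
            f_hat = feature_vector(K_pert, sheaf_factory(network, K_pert))
        scores.append(
            PerturbationScore(gene=gene, scale=scale, distance=_distance(f, f_hat, mode))
        )
    return scores


def score_all_genes(
    network: LabeledNetwork,
    complexes: Sequence[SimplicialComplex],
    scales: Sequence[int],
    sheaf_factory: SheafFactory = default_sheaf,
    mode: DistanceMode = "concatenated",
) -> list[PerturbationScore]:
    """Perturbation scores for every gene at every scale."""
    baseline = [feature_vector(K, sheaf_factory(network, K)) for K in complexes]
    out: list[PerturbationScore] = []
    for gene in network.genes:
        out.extend(
            score_gene(
                network, complexes, scales, gene,
                sheaf_factory=sheaf_factory, mode=mode, baseline=baseline,
            )
        )
    return out


def rank_and_intersect(
    scores: Iterable[PerturbationScore], top_k: int
) -> RankingResult:
    """Rank genes per scale by descending distance (ties: symbol ascending)
    and intersect the top-k prefixes over all scales.

    An empty intersection is legal; the per-scale lists are always reported.
    A frequency map (in how many scales' top-k each candidate appears) is
    attached for diagnostics.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    by_scale: dict[int, list[PerturbationScore]] = {}
    for s in scores:
        by_scale.setdefault(s.scale, []).append(s)

    genes_per_scale = {len({s.gene for s in v}) for v in by_scale.values()}
    if len(genes_per_scale) > 1:
        raise ValueError("every gene must be scored at every scale")

    per_scale: dict[int, list[str]] = {}
    prefixes: list[set[str]] = []
    for scale, scale_scores in sorted(by_scale.items()):
        ordered = sorted(scale_scores, key=lambda s: (-s.distance, s.gene))
        per_scale[scale] = [s.gene for s in ordered]
        prefixes.append(set(per_scale[scale][:top_k]))

    intersected = set.intersection(*prefixes) if prefixes else set()
    frequencies: dict[str, int] = {}
    for prefix in prefixes:
        for g in prefix:
            frequencies[g] = frequencies.get(g, 0) + 1
    return RankingResult(
        per_scale=per_scale,
        intersected=intersected,
        top_k=top_k,
        frequencies=dict(sorted(frequencies.items(), key=lambda kv: (-kv[1], kv[0]))),
    )
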