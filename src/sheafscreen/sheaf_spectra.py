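"""Cellular sheaf assignment, coboundaries, (persistent) sheaf Laplacians.

Every stalk is one-dimensional real, so a sheaf is determined by a strictly
positive vertex quantity ``q`` and a nowhere-zero simplex weight ``F``.  The
restriction map for a face relation tau <= sigma is the scalar

    F(tau) * (product of q over vertices of sigma not in tau) / F(sigma)

which reduces to multiplication by q_j / r_ij on a vertex-edge relation when
F(vertex) = 1 and F(edge) = r_ij.  The degree-q coboundary matrix has entry
(-1)**i * restriction(tau -> sigma) at (sigma, tau) when tau is sigma with
the vertex at position i removed, and

    L_q = D_q^T D_q + D_{q-1} D_{q-1}^T

is symmetric positive semidefinite.  With q ≡ 1 and F ≡ 1 ("constant sheaf")
L_0 is exactly the unnormalized graph Laplacian, and the nullity of L_q is
the q-th Betti number of the complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from sheafscreen.clique_filtration import Simplex, SimplicialComplex, faces
from sheafscreen.network_io import LabeledNetwork

#: Floor for the edge length derived from a confidence score.
DEFAULT_R_FLOOR = 1e-3
#: Relative tolerance below which an eigenvalue counts as zero.
DEFAULT_ZERO_TOL = 1e-8
#: Singular-value cutoff for the Schur-complement pseudo-inverse.
SCHUR_PINV_CUTOFF = 1e-10
#: Refuse eigendecompositions beyond this many simplices in one degree.
MAX_SIMPLICES_PER_DEGREE = 20_000


@dataclass(frozen=True)
class SheafAssignment:
    """One-dimensional sheaf data: vertex quantities and simplex weights."""

    q: Mapping[str, float]
    F: Callable[[Simplex], float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.q.values()):
            raise ValueError("all stalk quantities q must be strictly positive")

    def weight(self, simplex: Simplex) -> float:
        w = self.F(tuple(simplex))
        if w == 0:
            raise ValueError(f"F must be nowhere zero; F({simplex}) = 0")
        return w


@dataclass(frozen=True)
class SpectrumSummary:
    """Six summary statistics of one Laplacian's eigenvalue multiset."""

    min: float
    mean: float
    max: float
    std: float
    sum: float
    n_zero: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.min, self.mean, self.max, self.std, self.sum, float(self.n_zero)]
        )


def restriction_scalar(tau: Simplex, sigma: Simplex, sheaf: SheafAssignment) -> float:
    """Restriction-map scalar for the face relation tau <= sigma."""
    tau, sigma = tuple(tau), tuple(sigma)
    tau_set = set(tau)
    if not tau_set.issubset(sigma):
        raise ValueError(f"{tau} is not a face of {sigma}")
    if tau == sigma:
        return 1.0
    prod = math.prod(sheaf.q[v] for v in sigma if v not in tau_set)
    return sheaf.weight(tau) * prod / sheaf.weight(sigma)


def constant_sheaf(complex_: SimplicialComplex) -> SheafAssignment:
    """q ≡ 1, F ≡ 1; L0 reduces to the graph Laplacian."""
    return SheafAssignment(q={v: 1.0 for v in complex_.vertices}, F=lambda s: 1.0)


def default_sheaf(
    network: LabeledNetwork,
    complex_: SimplicialComplex,
    r_floor: float = DEFAULT_R_FLOOR,
) -> SheafAssignment:
    """Dysregulation-labeled sheaf.

    q comes from the network labels.  F(vertex) = 1; for k >= 1 the weight of
    a k-simplex is the mean edge length over its edges, with the edge length
    r_ij = max(1 - score_ij / 1000, r_floor) (high confidence = short edge).
    """
    missing = [v for v in complex_.vertices if v not in network.q]
    if missing:
        raise ValueError(f"complex vertices not in network: {missing}")

    def edge_length(a: str, b: str) -> float:
        score = network.score[(a, b) if a < b else (b, a)]
        return max(1.0 - score / 1000.0, r_floor)

    cache: dict[Simplex, float] = {}

    def F(simplex: Simplex) -> float:
        if len(simplex) == 1:
            return 1.0
        w = cache.get(simplex)
        if w is None:
            verts = list(simplex)
            lengths = [
                edge_length(verts[i], verts[j])
                for i in range(len(verts))
                for j in range(i + 1, len(verts))
            ]
            w = cache[simplex] = sum(lengths) / len(lengths)
        return w

    return SheafAssignment(q=dict(network.q), F=F)


def product_sheaf(network: LabeledNetwork, complex_: SimplicialComplex) -> SheafAssignment:
    """Alternative strategy: F(simplex) = product of q over its vertices."""
    q = dict(network.q)
    return SheafAssignment(q=q, F=lambda s: math.prod(q[v] for v in s))


SHEAF_STRATEGIES: dict[str, Callable[[LabeledNetwork, SimplicialComplex], SheafAssignment]] = {
    "default": default_sheaf,
    "product": product_sheaf,
    "constant": lambda network, complex_: constant_sheaf(complex_),
}


def coboundary_matrix(
    complex_: SimplicialComplex, sheaf: SheafAssignment, degree: int
) -> np.ndarray:
    """Degree-``degree`` coboundary: rows = (degree+1)-simplices, columns =
    degree-simplices; entries = incidence sign x restriction scalar."""
    rows = complex_.simplices(degree + 1)
    cols = complex_.simplices(degree)
    D = np.zeros((len(rows), len(cols)))
    for r, sigma in enumerate(rows):
        for i, tau in enumerate(faces(sigma)):
            D[r, complex_.ordinal(tau)] = ((-1) ** i) * restriction_scalar(
                tau, sigma, sheaf
            )
    return D


def sheaf_laplacian(
    complex_: SimplicialComplex, sheaf: SheafAssignment, degree: int
) -> np.ndarray:
    """L_q = up-term + down-term; 0x0 when the degree has no simplices."""
    n = complex_.n_simplices(degree)
    if n == 0:
        return np.zeros((0, 0))
    L = np.zeros((n, n))
    if degree < complex_.max_dim:
        D_up = coboundary_matrix(complex_, sheaf, degree)
        L += D_up.T @ D_up
    if degree > 0:
        D_down = coboundary_matrix(complex_, sheaf, degree - 1)
        L += D_down @ D_down.T
    return L


def persistent_sheaf_laplacian(
    K_small: SimplicialComplex,
    K_big: SimplicialComplex,
    sheaf: SheafAssignment,
    degree: int,
) -> np.ndarray:
    """Persistent Laplacian of a nested pair K_small ⊆ K_big.

    The up-term is the Schur complement of D^T D (D the degree-q coboundary of
    K_big) onto the columns indexed by K_small's q-simplices, eliminating the
    q-simplices present only in K_big; the down-term comes from K_small alone.
    Its nullity is the persistent Betti number of the pair.
    """
    if not K_small.is_subcomplex_of(K_big):
        raise ValueError("K_small is not a subcomplex of K_big")
    small_q = K_small.simplices(degree)
    n = len(small_q)
    if n == 0:
        return np.zeros((0, 0))

    L = np.zeros((n, n))
    if degree < K_big.max_dim and K_big.n_simplices(degree + 1) > 0:
        D = coboundary_matrix(K_big, sheaf, degree)
        M = D.T @ D
        keep = np.array([K_big.ordinal(s) for s in small_q])
        drop = np.array(
            [K_big.ordinal(s) for s in K_big.simplices(degree) if s not in K_small]
        )
        if drop.size == 0:
            L += M[np.ix_(keep, keep)]
        else:
            M_II = M[np.ix_(keep, keep)]
            M_IJ = M[np.ix_(keep, drop)]
            M_JJ = M[np.ix_(drop, drop)]
            L += M_II - M_IJ @ np.linalg.pinv(M_JJ, rcond=SCHUR_PINV_CUTOFF) @ M_IJ.T
    if degree > 0:
        D_down = coboundary_matrix(K_small, sheaf, degree - 1)
        L += D_down @ D_down.T
    return L


def spectrum(laplacian: np.ndarray) -> np.ndarray:
    """All eigenvalues of a symmetric Laplacian, ascending."""
    if laplacian.shape[0] == 0:
        return np.zeros(0)
    if laplacian.shape[0] > MAX_SIMPLICES_PER_DEGREE:
        raise ValueError(
            f"matrix of order {laplacian.shape[0]} exceeds the configured cap "
            f"{MAX_SIMPLICES_PER_DEGREE}"
        )
    return np.linalg.eigvalsh(laplacian)


def summarize_spectrum(
    eigenvalues: np.ndarray, zero_tol: float = DEFAULT_ZERO_TOL
) -> SpectrumSummary:
    """Six statistics of an eigenvalue multiset.

    std is the population standard deviation; n_zero counts eigenvalues
    lambda <= zero_tol * max(1, lambda_max).  An empty multiset yields the
    all-zero summary by convention.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        return SpectrumSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0)
    lam_max = float(ev.max())
    threshold = zero_tol * max(1.0, lam_max)
    return SpectrumSummary(
        min=float(ev.min()),
        mean=float(ev.mean()),
        max=lam_max,
        std=float(ev.std()),
        sum=float(ev.sum()),
        n_zero=int(np.count_nonzero(ev <= threshold)),
    )
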