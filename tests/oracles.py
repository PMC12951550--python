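"""Independent rational-rank homology oracle.

Builds boundary matrices directly from simplex lists (not via the package's
coboundary assembly) and computes exact ranks over the rationals with sympy.
Used to cross-check Laplacian nullities against (persistent) Betti numbers.
"""

from __future__ import annotations

from itertools import combinations

import sympy

Simplex = tuple[str, ...]


def boundary_matrix(simplices_q: list[Simplex], simplices_qm1: list[Simplex]) -> sympy.Matrix:
    """Integer boundary matrix: rows = (q-1)-simplices, columns = q-simplices."""
    index = {s: i for i, s in enumerate(simplices_qm1)}
    M = sympy.zeros(len(simplices_qm1), len(simplices_q))
    for col, s in enumerate(simplices_q):
        for i in range(len(s)):
            face = s[:i] + s[i + 1 :]
            M[index[face], col] = (-1) ** i
    return M


def _by_dim(simplices: list[Simplex], max_dim: int) -> dict[int, list[Simplex]]:
    out: dict[int, list[Simplex]] = {d: [] for d in range(max_dim + 1)}
    for s in simplices:
        out[len(s) - 1].append(tuple(s))
    for d in out:
        out[d] = sorted(set(out[d]))
    return out


def betti_numbers(simplices: list[Simplex], max_dim: int) -> list[int]:
    """Simplicial Betti numbers beta_0..beta_max_dim by exact rank-nullity."""
    groups = _by_dim(simplices, max_dim)
    rank = {}
    for q in range(1, max_dim + 1):
        rank[q] = boundary_matrix(groups[q], groups[q - 1]).rank() if groups[q] else 0
    rank[max_dim + 1] = 0
    betti = []
    for q in range(max_dim + 1):
        n_q = len(groups[q])
        betti.append(n_q - rank.get(q, 0) - rank.get(q + 1, 0))
    return betti


def persistent_betti(
    small: list[Simplex], big: list[Simplex], q: int, max_dim: int
) -> int:
    """Rank of the map H_q(K_small) -> H_q(K_big) over the rationals.

    beta = dim Z_q(small) - dim( Z_q(small) ∩ B_q(big) ), computed with the
    cycle space embedded into C_q(big) coordinates.
    """
    gs = _by_dim(small, max_dim)
    gb = _by_dim(big, max_dim)
    n_small = len(gs[q])
    if n_small == 0:
        return 0

    if q == 0:
        z_small = sympy.eye(n_small)  # every 0-chain is a cycle
    else:
        d_small = boundary_matrix(gs[q], gs[q - 1])
        null = d_small.nullspace()
        if not null:
            return 0
        z_small = sympy.Matrix.hstack(*null)
    dim_z = z_small.shape[1]

    # embed small q-chains into big q-chain coordinates
    big_index = {s: i for i, s in enumerate(gb[q])}
    embed = sympy.zeros(len(gb[q]), n_small)
    for j, s in enumerate(gs[q]):
        embed[big_index[s], j] = 1
    z_embedded = embed * z_small

    if q + 1 > max_dim or not gb[q + 1]:
        return dim_z
    d_next = boundary_matrix(gb[q + 1], gb[q])
    dim_b = d_next.rank()
    joint = sympy.Matrix.hstack(z_embedded, d_next)
    dim_sum = joint.rank()
    dim_intersection = dim_z + dim_b - dim_sum
    return dim_z - dim_intersection
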