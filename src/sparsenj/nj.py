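"""Canonical Neighbor Joining.

Used three ways by the sparse algorithm: as the accuracy baseline, to build
the initial backbone on the k0 sampled taxa, and to resolve the 4-taxon
quartets that steer each placement.  The implementation is the O(n^3)
textbook recursion — join the pair minimising D_ij - u_i - u_j with
u_i = sum_j D_ij / (n-2), then reduce the matrix with
D_(ij),k = (D_ik + D_jk - D_ij)/2 — vectorised over numpy rows.  Ties in
the join criterion are broken lexicographically on the active-index pair,
which makes every output deterministic.  Branch lengths are not computed:
only the topology is needed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .distances import DistanceOracle
from .tree import Topology

__all__ = ["nj_u", "nj_join_step", "neighbor_joining", "quartet_topology"]


def nj_u(matrix: np.ndarray) -> np.ndarray:
    """Per-taxon average row sums u_i = sum_{j != i} D_ij / (n-2)."""
    D = np.asarray(matrix, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("u values require at least 3 active taxa")
    return D.sum(axis=1) / (n - 2)


def _argmin_pair(D: np.ndarray) -> tuple[int, int]:
    """Lexicographically first argmin of the join criterion."""
    n = D.shape[0]
    u = nj_u(D)
    Q = D - u[:, None] - u[None, :]
    np.fill_diagonal(Q, np.inf)
    flat = int(np.argmin(Q))  # first occurrence, row-major = lexicographic
    i, j = divmod(flat, n)
    return (i, j) if i < j else (j, i)


def nj_join_step(matrix: np.ndarray) -> tuple[tuple[int, int], np.ndarray]:
    """One NJ agglomeration step.

    Returns the joined index pair (i, j) and the reduced matrix in which
    the new cluster occupies index i and index j is removed; remaining
    indices shift down accordingly.
    """
    D = np.asarray(matrix, dtype=float)
    i, j = _argmin_pair(D)
    keep = [k for k in range(D.shape[0]) if k != j]
    newrow = (D[i] + D[j] - D[i, j]) / 2.0
    out = D[np.ix_(keep, keep)].copy()
    pos = keep.index(i)
    out[pos, :] = newrow[keep]
    out[:, pos] = newrow[keep]
    out[pos, pos] = 0.0
    return (i, j), out


def neighbor_joining(source, taxa: Sequence[str] | None = None) -> Topology:
    """Full NJ tree from an oracle or a dense matrix.

    ``source`` is either a :class:`DistanceOracle` (all pairwise distances
    over ``taxa`` are queried — this is the dense subroutine the sparse
    method confines to small inputs) or an (n, n) matrix, in which case
    ``taxa`` names its rows.
    """
    if isinstance(source, DistanceOracle):
        names = list(taxa) if taxa is not None else list(source.taxa)
        D = source.matrix(names)
    else:
        if taxa is None:
            raise ValueError("taxa names are required with a matrix source")
        names = list(taxa)
        D = np.array(source, dtype=float)
    n = len(names)
    if n < 3 or D.shape != (n, n):
        raise ValueError("need >= 3 taxa and a matching square matrix")

    top = Topology(capacity=2 * n)
    nodes = []
    for name in names:
        v = top._new_node()
        top._set_leaf(v, name)
        nodes.append(v)

    D = D.copy()
    while len(nodes) > 3:
        (i, j) = _argmin_pair(D)
        w = top._new_node()
        top._link(w, nodes[i])
        top._link(w, nodes[j])
        newrow = (D[i] + D[j] - D[i, j]) / 2.0
        keep = [k for k in range(D.shape[0]) if k != j]
        D[i, :] = newrow
        D[:, i] = newrow
        D[i, i] = 0.0
        D = D[np.ix_(keep, keep)]
        nodes[i] = w
        nodes.pop(j)
    hub = top._new_node()
    for v in nodes:
        top._link(hub, v)
    return top


def quartet_topology(taxa4: Sequence[str], matrix4: np.ndarray
                     ) -> tuple[tuple[str, str], tuple[str, str]]:
    """Resolve a quartet by the first NJ join on its 4x4 matrix.

    Returns the two cherries of the split, e.g. ((a, b), (c, d)).  With an
    additive matrix this agrees with the four-point-condition minimiser.
    """
    names = list(taxa4)
    if len(names) != 4 or len(set(names)) != 4:
        raise ValueError("need 4 distinct taxa")
    D = np.asarray(matrix4, dtype=float)
    if D.shape != (4, 4):
        raise ValueError("matrix must be 4x4")
    i, j = _argmin_pair(D)
    rest = [k for k in range(4) if k not in (i, j)]
    return (names[i], names[j]), (names[rest[0]], names[rest[1]])
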