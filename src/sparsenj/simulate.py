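"""Synthetic phylogenies and Jukes–Cantor sequence evolution.

The generator reproduces a standard benchmark recipe: a random topology is
drawn by repeatedly merging two uniformly chosen components until one
remains; every branch length is an independent Exponential draw with mean
``scale`` (default 1e-3 expected substitutions per site); sequences then
evolve down the tree under the Jukes–Cantor model, where a site traversing
a branch of length t substitutes with probability (3/4)(1 - e^{-4t/3}) to a
uniformly chosen different base.

Exact path-length matrices (additive, satisfying the four-point condition)
are available for noiseless recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import SequenceMatrix
from .tree import Edge, Topology, to_newick

__all__ = [
    "WeightedTree",
    "random_topology",
    "draw_branch_lengths",
    "evolve_jc",
    "path_distance_matrix",
    "simulate_dataset",
]


@dataclass
class WeightedTree:
    """A topology with strictly positive per-edge branch lengths."""

    topology: Topology
    branch_lengths: dict[Edge, float]

    def __post_init__(self) -> None:
        for e, w in self.branch_lengths.items():
            if w < 0:
                raise ValueError(f"negative branch length on edge {e}")

    @property
    def min_branch_length(self) -> float:
        """The shortest branch — twice this is the noise radius within
        which distance-based recovery of the topology is guaranteed."""
        return min(self.branch_lengths.values())

    def to_newick(self) -> str:
        return to_newick(self.topology, self.branch_lengths)


def default_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"t{i:0{width}d}" for i in range(n)]


def random_topology(n: int, rng: np.random.Generator,
                    labels: list[str] | None = None) -> Topology:
    """Random unrooted bifurcating topology by uniform pairwise merging.

    Starts from n singleton components and repeatedly joins two uniformly
    chosen components under a fresh internal node; the final degree-2 node
    is suppressed to yield a valid unrooted tree.
    """
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if labels is None:
        labels = default_labels(n)
    if len(labels) != n:
        raise ValueError("label count must equal n")
    top = Topology(capacity=2 * n)
    handles = []
    for lab in labels:
        v = top._new_node()
        top._set_leaf(v, lab)
        handles.append(v)
    while len(handles) > 1:
        i, j = sorted(int(x) for x in rng.choice(len(handles), 2, replace=False))
        w = top._new_node()
        top._link(w, handles[i])
        top._link(w, handles[j])
        handles[i] = w
        handles[j] = handles[-1]  # O(1) swap-remove; j > i so i is safe
        handles.pop()
    root = handles[0]
    a, b = top.neighbors(root)
    top._unlink(root, a)
    top._unlink(root, b)
    top._link(a, b)
    top._free.append(root)
    top.validate()
    return top


def draw_branch_lengths(topology: Topology, scale: float = 1e-3,
                        rng: np.random.Generator | None = None) -> WeightedTree:
    """Attach i.i.d. Exponential(mean=scale) lengths to every edge."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if rng is None:
        rng = np.random.default_rng()
    edges = sorted(topology.edges())
    draws = rng.exponential(scale, size=len(edges))
    return WeightedTree(topology, dict(zip(edges, map(float, draws))))


def _jc_substitution_probability(t: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


def evolve_jc(weighted_tree: WeightedTree, m: int,
              rng: np.random.Generator, root: int | None = None) -> SequenceMatrix:
    """Evolve an m-site alignment down the tree under Jukes–Cantor.

    The root (an arbitrary internal node; JC is reversible so the choice
    does not affect the leaf joint distribution) draws its sequence i.i.d.
    uniform over {A,C,G,T}; each edge applies the exact per-site
    substitution probability for its length — no discretised steps.
    """
    if m < 1:
        raise ValueError("need at least one site")
    top = weighted_tree.topology
    lengths = weighted_tree.branch_lengths
    if root is None:
        root = min(v for v in top.nodes() if not top.is_leaf(v))
    seqs: dict[int, np.ndarray] = {
        root: rng.integers(0, 4, size=m, dtype=np.uint8)}
    out: dict[str, np.ndarray] = {}
    stack: list[tuple[int, int]] = [(root, -1)]
    while stack:
        v, par = stack.pop()
        sv = seqs.pop(v)
        if top.is_leaf(v):
            out[top.leaf_label(v)] = sv
            continue
        for u in sorted(top.neighbors(v)):
            if u == par:
                continue
            e = (v, u) if v < u else (u, v)
            p = _jc_substitution_probability(lengths[e])
            child = sv.copy()
            hit = rng.random(m) < p
            nhit = int(np.count_nonzero(hit))
            if nhit:
                child[hit] = (child[hit]
                              + rng.integers(1, 4, size=nhit, dtype=np.uint8)) % 4
            seqs[u] = child
            stack.append((u, v))
    taxa = top.leaves()
    return SequenceMatrix(taxa, np.vstack([out[t] for t in taxa]))


def path_distance_matrix(weighted_tree: WeightedTree):
    """Exact leaf-to-leaf path-length matrix as ``(matrix, taxa)``.

    Additive by construction: satisfies the four-point condition to
    machine precision.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import dijkstra

    top = weighted_tree.topology
    size = max(top.nodes()) + 1
    rows, cols, vals = [], [], []
    for (u, v), w in weighted_tree.branch_lengths.items():
        rows += [u, v]
        cols += [v, u]
        vals += [w, w]
    g = csr_matrix((vals, (rows, cols)), shape=(size, size))
    taxa = top.leaves()
    leaf_ids = [top.leaf_node(t) for t in taxa]
    full = dijkstra(g, directed=False, indices=leaf_ids)
    return full[:, leaf_ids], taxa


def simulate_dataset(n: int, m: int, seed: int, bl_scale: float = 1e-3):
    """One-call benchmark dataset: (WeightedTree, SequenceMatrix).

    Reproducible from ``seed``; topology, branch lengths and sequence
    evolution consume independent substreams.
    """
    ss = np.random.SeedSequence(seed)
    s_top, s_bl, s_seq = ss.spawn(3)
    top = random_topology(n, np.random.default_rng(s_top))
    wt = draw_branch_lengths(top, bl_scale, np.random.default_rng(s_bl))
    seqs = evolve_jc(wt, m, np.random.default_rng(s_seq))
    return wt, seqs
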