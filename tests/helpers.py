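"""Independent brute-force oracles and tree builders used across the tests.

Everything here deliberately avoids the package's optimised code paths:
splits are computed with plain set operations over an adjacency traversal,
quartets by split restriction, transfer indices by exhaustive edge scans —
so that agreement with the package is a genuine two-route check.
"""

from __future__ import annotations

import itertools

import numpy as np

from sparsenj.simulate import draw_branch_lengths, random_topology
from sparsenj.tree import Topology, from_newick


# ----------------------------------------------------------------------
# split machinery (set-based, independent of sparsenj.metrics bitmasks)
# ----------------------------------------------------------------------

def side_labels(tree: Topology, a: int, b: int) -> frozenset[str]:
    """Leaf labels reachable from ``a`` without crossing the edge (a, b)."""
    seen = {a, b}
    stack = [a]
    out = set()
    while stack:
        v = stack.pop()
        if tree.is_leaf(v):
            out.add(tree.leaf_label(v))
        for u in tree.neighbors(v):
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return frozenset(out)


def all_edge_splits(tree: Topology, include_trivial: bool = False):
    """List of (edge, side) with ``side`` canonical: not containing the
    alphabetically first taxon."""
    first = min(tree.leaves())
    n = tree.n_leaves
    out = []
    for (u, v) in tree.edges():
        side = side_labels(tree, u, v)
        if first in side:
            side = frozenset(tree.leaves()) - side
        if include_trivial or 2 <= len(side) <= n - 2:
            out.append(((u, v), side))
    return out


def splits_of(tree: Topology) -> frozenset[frozenset[str]]:
    return frozenset(s for _, s in all_edge_splits(tree))


def brute_rf(a: Topology, b: Topology) -> float:
    sa, sb = splits_of(a), splits_of(b)
    return 1.0 - len(sa & sb) / (a.n_leaves - 3)


def brute_transfer_index(side: set[str], tree: Topology) -> tuple[int, float]:
    taxa = set(tree.leaves())
    n = len(taxa)
    side = frozenset(side)
    best = n
    for _, s in all_edge_splits(tree, include_trivial=True):
        for cand in (s, taxa - s):
            best = min(best, len(side ^ cand))
    return best, best / min(len(side), n - len(side))


def brute_transfer_distance(ref: Topology, inf: Topology) -> float:
    vals = [brute_transfer_index(set(s), inf)[1] for _, s in all_edge_splits(ref)]
    return sum(vals) / len(vals)


def induced_quartet(splits, quad: frozenset[str]):
    """Cherry pairing of a 4-taxon subset from a tree's splits, or None
    when unresolved."""
    for s in splits:
        inter = s & quad
        if len(inter) == 2:
            return frozenset({frozenset(inter), frozenset(quad - inter)})
    return None


def brute_quartet_distance(a: Topology, b: Topology) -> float:
    taxa = sorted(a.leaves())
    sa, sb = splits_of(a), splits_of(b)
    differ = total = 0
    for quad in itertools.combinations(taxa, 4):
        q = frozenset(quad)
        qa, qb = induced_quartet(sa, q), induced_quartet(sb, q)
        total += 1
        if qa is None or qb is None or qa != qb:
            differ += 1
    return differ / total


def bfs_edge_displacement(tree: Topology, ea, eb) -> int:
    """Edges strictly between two edges, via BFS in the line graph."""
    ea = tuple(sorted(ea))
    eb = tuple(sorted(eb))
    if ea == eb:
        return 0
    dist = {ea: 0}
    frontier = [ea]
    while frontier:
        nxt = []
        for e in frontier:
            for v in e:
                for u in tree.neighbors(v):
                    f = tuple(sorted((v, u)))
                    if f not in dist:
                        dist[f] = dist[e] + 1
                        if f == eb:
                            return dist[f] - 1
                        nxt.append(f)
        frontier = nxt
    raise AssertionError("edges not connected")


# ----------------------------------------------------------------------
# tree builders
# ----------------------------------------------------------------------

def caterpillar(labels) -> Topology:
    labels = list(labels)
    core = f"({labels[0]},{labels[1]})"
    for lab in labels[2:-1]:
        core = f"({core},{lab})"
    return from_newick(f"({core},{labels[-1]});")


def all_topologies(labels) -> list[Topology]:
    """Every unrooted bifurcating topology on the given labels."""
    labels = list(labels)
    trees = [Topology.star(labels[:3])]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            for e in t.edges():
                t2 = t.copy()
                t2.insert_leaf(e, lab)
                nxt.append(t2)
        trees = nxt
    return trees


def random_weighted(n: int, rng: np.random.Generator, scale: float = 1e-3):
    top = random_topology(n, rng)
    return draw_branch_lengths(top, scale, rng)
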