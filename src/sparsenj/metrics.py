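"""Tree-comparison metrics: Robinson–Foulds, transfer and quartet distances,
plus the per-insertion edge-displacement statistic.

RF only checks whether bipartitions are identical, so it saturates quickly;
the transfer distance instead asks, per reference edge, how many taxa must
switch sides to match the *closest* inferred edge (normalised by the
smaller side of the reference bipartition) and averages over reference
edges.  The quartet distance is the proportion of 4-taxon subsets whose
induced topology differs between the trees — exact for small trees,
Monte-Carlo sampled with a reported standard error for large ones.

Bipartitions are manipulated as integer bitmasks over a fixed taxon order,
canonically encoded as the side not containing the first taxon.  Inferred
trees from this package are bifurcating; multifurcating reference trees
(e.g. consensus trees read from Newick via dendropy) are accepted, with
unresolved quadruples counted as differing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np

from .tree import Edge, Topology

__all__ = [
    "ComparisonReport",
    "QuartetResult",
    "rf_distance",
    "transfer_index",
    "transfer_distance",
    "quartet_distance",
    "edge_displacement",
    "compare_trees",
]


# ----------------------------------------------------------------------
# generic tree graphs (Topology or dendropy.Tree)
# ----------------------------------------------------------------------

def _graph(tree) -> tuple[dict[int, list[int]], dict[str, int]]:
    """(adjacency, leaf-label -> node) for a Topology or dendropy Tree."""
    if isinstance(tree, Topology):
        adj = {v: list(tree.neighbors(v)) for v in tree.nodes()}
        leaf = {lab: v for v, lab in tree.leaf_labels.items()}
        return adj, leaf
    import dendropy

    if isinstance(tree, dendropy.Tree):
        adj: dict[int, list[int]] = {}
        leaf: dict[str, int] = {}
        ids: dict[int, int] = {}
        for nd in tree.preorder_node_iter():
            ids[id(nd)] = len(ids)
        for nd in tree.preorder_node_iter():
            v = ids[id(nd)]
            adj.setdefault(v, [])
            if nd.parent_node is not None:
                p = ids[id(nd.parent_node)]
                adj[v].append(p)
                adj[p].append(v)
            if nd.is_leaf():
                leaf[nd.taxon.label] = v
        # suppress degree-2 nodes (rooted inputs)
        for v, nbrs in list(adj.items()):
            if len(nbrs) == 2 and v not in leaf.values():
                a, b = nbrs
                adj[a] = [b if x == v else x for x in adj[a]]
                adj[b] = [a if x == v else x for x in adj[b]]
                del adj[v]
        return adj, leaf
    raise TypeError(f"unsupported tree type {type(tree)!r}")


def _taxa_index(leaf_map: dict[str, int]) -> dict[str, int]:
    return {t: i for i, t in enumerate(sorted(leaf_map))}


def _split_masks(adj, leaf_map, tindex, include_trivial=False) -> list[int]:
    """Bitmasks of the bipartitions implied by edges, canonically encoded
    as the side not containing taxon index 0."""
    n = len(tindex)
    full = (1 << n) - 1
    ref_label = min(tindex, key=tindex.get)
    root = leaf_map[ref_label]
    masks: list[int] = []
    below: dict[int, int] = {}
    leaf_bits = {v: 1 << tindex[lab] for lab, v in leaf_map.items()}
    order: list[int] = []
    parent = {root: -1}
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for u in adj[v]:
            if u != parent[v]:
                parent[u] = v
                stack.append(u)
    for v in reversed(order):
        m = leaf_bits.get(v, 0)
        for u in adj[v]:
            if u != parent[v]:
                m |= below[u]
        below[v] = m
    for v in order[1:]:  # one edge per non-root node
        m = below[v]
        if m & 1:
            m ^= full
        pc = m.bit_count()
        if include_trivial or 2 <= pc <= n - 2:
            masks.append(m)
    return masks


def _check_same_leaves(la: dict[str, int], lb: dict[str, int]) -> list[str]:
    if set(la) != set(lb):
        raise ValueError("trees are over different leaf sets")
    taxa = sorted(la)
    if len(taxa) < 4:
        raise ValueError("need at least 4 shared leaves")
    return taxa


# ----------------------------------------------------------------------
# Robinson–Foulds
# ----------------------------------------------------------------------

def rf_distance(tree_a, tree_b) -> float:
    """Normalised RF distance: 1 - (shared non-trivial splits) / (n - 3)."""
    ga, la = _graph(tree_a)
    gb, lb = _graph(tree_b)
    taxa = _check_same_leaves(la, lb)
    tindex = {t: i for i, t in enumerate(taxa)}
    sa = set(_split_masks(ga, la, tindex))
    sb = set(_split_masks(gb, lb, tindex))
    return 1.0 - len(sa & sb) / (len(taxa) - 3)


# ----------------------------------------------------------------------
# transfer distance
# ----------------------------------------------------------------------

def _transfer_count(ref_mask: int, inferred_masks: list[int], n: int) -> int:
    best = n
    for m in inferred_masks:
        x = (ref_mask ^ m).bit_count()
        if x > n - x:
            x = n - x
        if x < best:
            best = x
            if best == 0:
                break
    return best


def transfer_index(reference_split, inferred_tree) -> tuple[int, float]:
    """Minimal number of taxa to move across the closest inferred edge to
    match the reference bipartition, and that count normalised by the
    smaller side of the reference split.

    ``reference_split`` is one side of the bipartition, as an iterable of
    taxon names.  All inferred edges, trivial ones included, compete.
    """
    g, leaf = _graph(inferred_tree)
    taxa = sorted(leaf)
    n = len(taxa)
    tindex = {t: i for i, t in enumerate(taxa)}
    side = set(reference_split)
    if not side <= set(taxa):
        raise ValueError("reference split names unknown taxa")
    size = len(side)
    if size in (0, n):
        raise ValueError("reference split is trivial")
    mask = 0
    for t in side:
        mask |= 1 << tindex[t]
    if mask & 1:
        mask ^= (1 << n) - 1
    inferred = _split_masks(g, leaf, tindex, include_trivial=True)
    count = _transfer_count(mask, inferred, n)
    return count, count / min(size, n - size)


def transfer_distance(reference_tree, inferred_tree) -> float:
    """Mean normalised transfer index over the reference's non-trivial
    edges."""
    gr, lr = _graph(reference_tree)
    gi, li = _graph(inferred_tree)
    taxa = _check_same_leaves(lr, li)
    n = len(taxa)
    tindex = {t: i for i, t in enumerate(taxa)}
    ref_masks = _split_masks(gr, lr, tindex)
    inf_masks = _split_masks(gi, li, tindex, include_trivial=True)
    total = 0.0
    for m in ref_masks:
        pc = m.bit_count()
        count = _transfer_count(m, inf_masks, n)
        total += count / min(pc, n - pc)
    return total / len(ref_masks)


# ----------------------------------------------------------------------
# quartet distance
# ----------------------------------------------------------------------

@dataclass
class QuartetResult:
    value: float
    se: float
    n_quartets: int
    exact: bool

    def __float__(self) -> float:  # pragma: no cover
        return self.value


def _leaf_topo_dists(adj, leaf_map, taxa) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    nodes = sorted(adj)
    remap = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for v, nbrs in adj.items():
        for u in nbrs:
            rows.append(remap[v])
            cols.append(remap[u])
    g = csr_matrix((np.ones(len(rows)), (rows, cols)),
                   shape=(len(nodes), len(nodes)))
    leaf_ids = [remap[leaf_map[t]] for t in taxa]
    D = shortest_path(g, unweighted=True, directed=False, indices=leaf_ids)
    return D[:, leaf_ids].astype(np.int32)


def _quartet_codes(D: np.ndarray, i, j, k, l) -> np.ndarray:
    """Induced quartet topology per quadruple: 0 -> ij|kl, 1 -> ik|jl,
    2 -> il|jk, -1 -> unresolved (multifurcation)."""
    s = np.stack([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]])
    t = np.argmin(s, axis=0)
    srt = np.sort(s, axis=0)
    return np.where(srt[0] == srt[1], -1, t)


def quartet_distance(tree_a, tree_b, mode: str = "auto",
                     n_samples: int = 500_000,
                     rng: np.random.Generator | None = None,
                     exact_limit: int = 30) -> QuartetResult:
    """Proportion of 4-taxon subsets with differing induced topologies.

    ``mode`` is "exact" (all C(n,4) quadruples; refused above
    ``exact_limit`` leaves), "sample" (uniform quadruples, binomial
    standard error reported) or "auto".  Unresolved quadruples, which only
    arise from multifurcating inputs, count as differing.
    """
    ga, la = _graph(tree_a)
    gb, lb = _graph(tree_b)
    taxa = _check_same_leaves(la, lb)
    n = len(taxa)
    if mode == "auto":
        mode = "exact" if n <= exact_limit else "sample"
    if mode == "exact" and n > exact_limit:
        raise ValueError(f"exact quartet distance refused for n = {n} > "
                         f"{exact_limit}; use mode='sample'")
    Da = _leaf_topo_dists(ga, la, taxa)
    Db = _leaf_topo_dists(gb, lb, taxa)
    if mode == "exact":
        quad = np.asarray(list(itertools.combinations(range(n), 4)),
                          dtype=np.int64)
    elif mode == "sample":
        if rng is None:
            rng = np.random.default_rng(0)
        got = []
        need = n_samples
        while need > 0:
            draw = rng.integers(0, n, size=(int(need * 1.2) + 8, 4))
            srt = np.sort(draw, axis=1)
            ok = np.all(np.diff(srt, axis=1) > 0, axis=1)
            got.append(draw[ok][:need])
            need -= got[-1].shape[0]
        quad = np.vstack(got)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    i, j, k, l = quad.T
    ta = _quartet_codes(Da, i, j, k, l)
    tb = _quartet_codes(Db, i, j, k, l)
    differ = (ta != tb) | (ta < 0) | (tb < 0)
    p = float(np.mean(differ))
    m = quad.shape[0]
    se = 0.0 if mode == "exact" else float(np.sqrt(p * (1 - p) / m))
    return QuartetResult(value=p, se=se, n_quartets=m, exact=(mode == "exact"))


# ----------------------------------------------------------------------
# edge displacement
# ----------------------------------------------------------------------

def edge_displacement(tree: Topology, edge_a: Edge, edge_b: Edge) -> int:
    """Number of edges strictly between two edges of the same tree
    (0 for identical or node-sharing edges)."""
    for (u, v) in (edge_a, edge_b):
        if not tree.has_edge(u, v):
            raise ValueError(f"edge ({u}, {v}) not in tree")
    src = set(edge_a)
    dst = set(edge_b)
    if src & dst:
        return 0
    dist = {v: 0 for v in src}
    frontier = list(src)
    while frontier:
        nxt = []
        for v in frontier:
            for u in tree.neighbors(v):
                if u not in dist:
                    dist[u] = dist[v] + 1
                    if u in dst:
                        return dist[u]
                    nxt.append(u)
        frontier = nxt
    raise ValueError("edges are not connected")  # pragma: no cover


# ----------------------------------------------------------------------
# aggregated report
# ----------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """RF / transfer / quartet distances between an inferred tree and a
    reference, all normalised to [0, 1] (zero iff identical split sets)."""

    n: int
    rf: float | None = None
    transfer: float | None = None
    quartet: float | None = None
    quartet_se: float | None = None
    quartet_exact: bool | None = None
    quartet_samples: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def compare_trees(reference, inferred,
                  metrics: tuple[str, ...] = ("rf", "transfer", "quartet"),
                  quartet_mode: str = "auto", quartet_samples: int = 500_000,
                  seed: int = 0) -> ComparisonReport:
    """One-call comparison of an inferred tree against a reference."""
    _, la = _graph(reference)
    report = ComparisonReport(n=len(la), seed=seed)
    if "rf" in metrics:
        report.rf = rf_distance(reference, inferred)
    if "transfer" in metrics:
        report.transfer = transfer_distance(reference, inferred)
    if "quartet" in metrics:
        q = quartet_distance(reference, inferred, mode=quartet_mode,
                             n_samples=quartet_samples,
                             rng=np.random.default_rng(seed))
        report.quartet = q.value
        report.quartet_se = q.se
        report.quartet_exact = q.exact
        report.quartet_samples = q.n_quartets
    return report
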