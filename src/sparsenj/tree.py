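"""Unrooted bifurcating tree topologies and the centroid-decomposition machinery.

The :class:`Topology` is the central container of the package: an unrooted
tree whose internal nodes all have degree 3 and whose leaves carry taxon
labels.  It is array-backed (an ``(capacity, 3)`` int32 neighbour table) so
that the traversal-heavy centroid recursion scales to tens of thousands of
taxa; the numba kernels in :mod:`sparsenj._kernels` operate directly on these
arrays.

A :class:`SubtreeView` is a connected subset of backbone edges — the unit of
the centroid recursion used for incremental leaf placement.  Views produced
by :func:`decompose` during the recursion use a compact representation
(an anchor node plus the set of removed centroids); views may also be built
from an explicit edge set, in which case a generic pure-Python backend with
identical tie rules is used.

Conventions
-----------
* Node ids are stable non-negative integers assigned at creation.
* An edge is an unordered pair, canonically written ``(min(u, v), max(u, v))``.
* Newick output orders children by smallest descendant label, omits branch
  lengths unless given explicitly, and is byte-stable under round-trips.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from ._kernels import centroid_scan, component_scan

__all__ = [
    "Topology",
    "SubtreeView",
    "StructuralError",
    "find_centroid",
    "decompose",
    "sample_leaves",
    "to_newick",
    "from_newick",
]

Edge = tuple[int, int]


class StructuralError(ValueError):
    """A tree or view violates a structural precondition."""


def _edge(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


class _Workspace:
    """Reusable scratch arrays for the numba kernels, one per Topology."""

    __slots__ = ("visit", "token", "stack", "order", "parent", "leafcnt",
                 "blocked", "nomask", "leafbuf", "blocked_ids")

    def __init__(self, cap: int) -> None:
        self.visit = np.zeros(cap, dtype=np.int64)
        self.token = 0
        self.stack = np.empty(cap, dtype=np.int32)
        self.order = np.empty(cap, dtype=np.int32)
        self.parent = np.empty(cap, dtype=np.int32)
        self.leafcnt = np.empty(cap, dtype=np.int32)
        self.blocked = np.zeros(cap, dtype=np.uint8)
        self.nomask = np.zeros(cap, dtype=np.uint8)
        self.leafbuf = np.empty(cap, dtype=np.int32)
        self.blocked_ids: tuple[int, ...] = ()

    def next_token(self) -> int:
        self.token += 1
        return self.token

    def sync_blocked(self, ids: tuple[int, ...]) -> None:
        if ids != self.blocked_ids:
            for v in self.blocked_ids:
                self.blocked[v] = 0
            for v in ids:
                self.blocked[v] = 1
            self.blocked_ids = ids


class Topology:
    """Unrooted bifurcating tree over labelled leaves.

    For k >= 3 leaves the tree has exactly 2k-2 nodes and 2k-3 edges; every
    internal node has degree 3 and every leaf degree 1.  Mutating methods
    (:meth:`insert_leaf`, :meth:`remove_leaf`) operate in place; use
    :meth:`copy` to branch off variants.
    """

    __slots__ = ("_nbr", "_deg", "_free", "_n_alloc", "_leaf_label",
                 "_label_node", "_ws")

    def __init__(self, capacity: int = 16) -> None:
        capacity = max(capacity, 8)
        self._nbr = np.full((capacity, 3), -1, dtype=np.int32)
        self._deg = np.zeros(capacity, dtype=np.int32)
        self._free: list[int] = []
        self._n_alloc = 0
        self._leaf_label: dict[int, str] = {}
        self._label_node: dict[str, int] = {}
        self._ws: _Workspace | None = None

    # ------------------------------------------------------------------
    # construction primitives (used by the package's builders)
    # ------------------------------------------------------------------
    def _grow(self) -> None:
        cap = self._nbr.shape[0] * 2
        nbr = np.full((cap, 3), -1, dtype=np.int32)
        nbr[: self._nbr.shape[0]] = self._nbr
        self._nbr = nbr
        deg = np.zeros(cap, dtype=np.int32)
        deg[: self._deg.shape[0]] = self._deg
        self._deg = deg
        self._ws = None

    def _new_node(self) -> int:
        if self._free:
            return self._free.pop()
        if self._n_alloc == self._nbr.shape[0]:
            self._grow()
        v = self._n_alloc
        self._n_alloc += 1
        return v

    def _link(self, u: int, v: int) -> None:
        for a, b in ((u, v), (v, u)):
            row = self._nbr[a]
            for s in range(3):
                if row[s] < 0:
                    row[s] = b
                    break
            else:  # pragma: no cover - guarded by degree invariant
                raise StructuralError(f"node {a} already has degree 3")
            self._deg[a] += 1

    def _unlink(self, u: int, v: int) -> None:
        for a, b in ((u, v), (v, u)):
            row = self._nbr[a]
            for s in range(3):
                if row[s] == b:
                    row[s] = -1
                    break
            else:
                raise StructuralError(f"edge ({u}, {v}) not present")
            self._deg[a] -= 1

    def _set_leaf(self, node: int, label: str) -> None:
        if label in self._label_node:
            raise ValueError(f"duplicate leaf label {label!r}")
        if not label:
            raise ValueError("leaf labels must be non-empty")
        self._leaf_label[node] = label
        self._label_node[label] = node

    @classmethod
    def star(cls, labels: Sequence[str]) -> "Topology":
        """The unique (star) topology on exactly three taxa."""
        if len(labels) != 3:
            raise ValueError("star topology requires exactly 3 labels")
        top = cls()
        hub = top._new_node()
        for lab in labels:
            v = top._new_node()
            top._link(hub, v)
            top._set_leaf(v, lab)
        return top

    @classmethod
    def quartet(cls, pair_a: Sequence[str], pair_b: Sequence[str]) -> "Topology":
        """Four-taxon topology with cherries ``pair_a`` and ``pair_b``."""
        top = cls()
        x = top._new_node()
        y = top._new_node()
        top._link(x, y)
        for hub, pair in ((x, pair_a), (y, pair_b)):
            for lab in pair:
                v = top._new_node()
                top._link(hub, v)
                top._set_leaf(v, lab)
        return top

    # ------------------------------------------------------------------
    # inspection
    # ------------------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self._leaf_label)

    @property
    def n_nodes(self) -> int:
        return self._n_alloc - len(self._free)

    @property
    def n_edges(self) -> int:
        return int(self._deg.sum()) // 2

    @property
    def leaf_labels(self) -> dict[int, str]:
        """Mapping from leaf node id to taxon name (a copy)."""
        return dict(self._leaf_label)

    def leaves(self) -> list[str]:
        return sorted(self._label_node)

    def leaf_node(self, label: str) -> int:
        try:
            return self._label_node[label]
        except KeyError:
            raise KeyError(f"unknown taxon {label!r}") from None

    def leaf_label(self, node: int) -> str:
        return self._leaf_label[node]

    def is_leaf(self, node: int) -> bool:
        return node in self._leaf_label

    def degree(self, node: int) -> int:
        return int(self._deg[node])

    def neighbors(self, node: int) -> tuple[int, ...]:
        return tuple(int(u) for u in self._nbr[node] if u >= 0)

    def nodes(self) -> list[int]:
        free = set(self._free)
        return [v for v in range(self._n_alloc) if v not in free]

    def internal_nodes(self) -> list[int]:
        return [v for v in self.nodes() if v not in self._leaf_label]

    def has_edge(self, u: int, v: int) -> bool:
        if not (0 <= u < self._n_alloc and 0 <= v < self._n_alloc):
            return False
        return bool((self._nbr[u] == v).any())

    def edges(self) -> list[Edge]:
        out = []
        for v in self.nodes():
            for u in self._nbr[v]:
                if u > v:
                    out.append((v, int(u)))
        return out

    # ------------------------------------------------------------------
    # mutation
    # ------------------------------------------------------------------
    def insert_leaf(self, edge: Edge, label: str) -> int:
        """Subdivide ``edge`` with a new internal node and attach a new leaf.

        Returns the new leaf's node id.  The tree grows from k to k+1
        leaves (two new nodes, two net new edges).
        """
        u, v = edge
        if not self.has_edge(u, v):
            raise StructuralError(f"edge ({u}, {v}) not in tree")
        if label in self._label_node:
            raise ValueError(f"duplicate leaf label {label!r}")
        w = self._new_node()
        x = self._new_node()
        self._unlink(u, v)
        self._link(u, w)
        self._link(w, v)
        self._link(w, x)
        self._set_leaf(x, label)
        return x

    def remove_leaf(self, label: str) -> Edge:
        """Remove a leaf and suppress its degree-2 attachment node.

        Returns the merged backbone edge.  Requires at least 4 leaves, so
        the result (a 3-leaf star at minimum) is still a valid topology.
        """
        if self.n_leaves < 4:
            raise StructuralError("cannot remove a leaf from a tree with < 4 leaves")
        x = self.leaf_node(label)
        (w,) = self.neighbors(x)
        self._unlink(w, x)
        a, b = self.neighbors(w)
        self._unlink(w, a)
        self._unlink(w, b)
        self._link(a, b)
        del self._leaf_label[x]
        del self._label_node[label]
        self._free.extend((x, w))
        return _edge(a, b)

    def copy(self) -> "Topology":
        top = Topology.__new__(Topology)
        top._nbr = self._nbr.copy()
        top._deg = self._deg.copy()
        top._free = list(self._free)
        top._n_alloc = self._n_alloc
        top._leaf_label = dict(self._leaf_label)
        top._label_node = dict(self._label_node)
        top._ws = None
        return top

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`StructuralError` on any invariant violation."""
        k = self.n_leaves
        nodes = self.nodes()
        if k < 3:
            raise StructuralError("a Topology needs at least 3 leaves")
        if len(nodes) != 2 * k - 2 or self.n_edges != 2 * k - 3:
            raise StructuralError("node/edge counts off for a bifurcating tree")
        for v in nodes:
            d = self.degree(v)
            if self.is_leaf(v):
                if d != 1:
                    raise StructuralError(f"leaf {v} has degree {d}")
            elif d != 3:
                raise StructuralError(f"internal node {v} has degree {d}")
        # connectivity (acyclicity follows from the edge count)
        seen = {nodes[0]}
        stack = [nodes[0]]
        while stack:
            v = stack.pop()
            for u in self.neighbors(v):
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        if len(seen) != len(nodes):
            raise StructuralError("tree is disconnected")

    # ------------------------------------------------------------------
    # workspace access for the kernels
    # ------------------------------------------------------------------
    def _workspace(self) -> _Workspace:
        cap = self._nbr.shape[0]
        if self._ws is None or self._ws.visit.shape[0] != cap:
            self._ws = _Workspace(cap)
        return self._ws

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Topology with {self.n_leaves} leaves, {self.n_edges} edges>"


# ----------------------------------------------------------------------
# Subtree views
# ----------------------------------------------------------------------

class SubtreeView:
    """A connected subset of backbone edges, the unit of centroid recursion.

    Recursion-generated views store an *anchor* node plus the tuple of
    blocked (removed-centroid) nodes; the view is then the set of backbone
    edges incident to the component of unblocked nodes containing the
    anchor.  Views may instead wrap an explicit edge set.  ``cover``
    describes the backbone component that covers the view when the view has
    no leaves of its own: a pair ``(entry, avoid)`` meaning "the backbone
    component reached from node *entry* without crossing node *avoid*".
    """

    __slots__ = ("backbone", "_edges", "_anchor", "_blocked", "_cover",
                 "_stats", "_leafnodes", "_scan_token")

    def __init__(self, backbone: Topology, *, edges: frozenset[Edge] | None = None,
                 anchor: int | None = None, blocked: tuple[int, ...] = (),
                 cover: tuple[int, int] | None = None) -> None:
        if (edges is None) == (anchor is None):
            raise ValueError("give either an explicit edge set or an anchor")
        self.backbone = backbone
        self._edges = edges
        self._anchor = anchor
        self._blocked = tuple(sorted(blocked))
        self._cover = cover
        self._stats: tuple[int, int] | None = None  # (n_edges, n_leaves)
        self._leafnodes: np.ndarray | None = None
        self._scan_token = -1  # workspace token of the last scan of this view

    # -- constructors ---------------------------------------------------
    @classmethod
    def whole(cls, backbone: Topology) -> "SubtreeView":
        anchor = min(backbone.nodes())
        return cls(backbone, anchor=anchor)

    @classmethod
    def from_edges(cls, backbone: Topology, edges: Iterable[Edge],
                   cover: tuple[int, int] | None = None) -> "SubtreeView":
        es = frozenset(_edge(u, v) for u, v in edges)
        for u, v in es:
            if not backbone.has_edge(u, v):
                raise StructuralError(f"edge ({u}, {v}) not in backbone")
        return cls(backbone, edges=es, cover=cover)

    @property
    def is_fast(self) -> bool:
        return self._anchor is not None and self._edges is None

    # -- stats ----------------------------------------------------------
    def _compute_fast(self) -> None:
        top = self.backbone
        ws = top._workspace()
        ws.sync_blocked(self._blocked)
        n_leaves, n_edges, _ = component_scan(
            top._nbr, top._deg, ws.blocked, -1, self._anchor,
            ws.visit, ws.next_token(), ws.stack, ws.leafbuf)
        self._stats = (int(n_edges), int(n_leaves))
        self._leafnodes = ws.leafbuf[:n_leaves].copy()

    def _explicit_adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {}
        for u, v in self._edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        # connectivity check over the view's edges
        if adj:
            start = next(iter(adj))
            seen = {start}
            stack = [start]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if len(seen) != len(adj):
                raise StructuralError("view edge set is disconnected")
        return adj

    def _compute_explicit(self) -> None:
        adj = self._explicit_adjacency()
        top = self.backbone
        leaves = sorted(v for v, nb_ in adj.items()
                        if len(nb_) == 1 and top.is_leaf(v))
        self._stats = (len(self._edges), len(leaves))
        self._leafnodes = np.asarray(leaves, dtype=np.int32)

    def _ensure_stats(self) -> None:
        if self._stats is None:
            if self.is_fast:
                self._compute_fast()
            else:
                self._compute_explicit()

    @property
    def edge_count(self) -> int:
        self._ensure_stats()
        return self._stats[0]

    @property
    def leaf_count(self) -> int:
        self._ensure_stats()
        return self._stats[1]

    @property
    def leaf_nodes(self) -> np.ndarray:
        """View leaf node ids, in deterministic traversal order."""
        self._ensure_stats()
        return self._leafnodes

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.backbone.leaf_label(int(v)) for v in self.leaf_nodes)

    @property
    def edge_set(self) -> frozenset[Edge]:
        if self._edges is not None:
            return self._edges
        # materialise from the fast representation (test/debug path)
        top = self.backbone
        ws = top._workspace()
        ws.sync_blocked(self._blocked)
        token = ws.next_token()
        component_scan(top._nbr, top._deg, ws.blocked, -1, self._anchor,
                       ws.visit, token, ws.stack, ws.leafbuf)
        out = set()
        for v in top.nodes():
            if ws.visit[v] == token and ws.blocked[v] == 0:
                for u in top.neighbors(v):
                    out.add(_edge(v, u))
        return frozenset(out)

    @property
    def covering_component(self) -> tuple[int, int] | None:
        return self._cover

    @property
    def covering_leaf_nodes(self) -> np.ndarray | None:
        """Leaf ids of the backbone component covering an empty-leaf view."""
        if self._cover is None:
            return None
        entry, avoid = self._cover
        top = self.backbone
        ws = top._workspace()
        if top.is_leaf(entry):
            return np.asarray([entry], dtype=np.int32)
        n_leaves, _, _ = component_scan(
            top._nbr, top._deg, ws.nomask, avoid, entry,
            ws.visit, ws.next_token(), ws.stack, ws.leafbuf)
        return ws.leafbuf[:n_leaves].copy()

    @property
    def single_edge(self) -> Edge:
        """The one edge of a terminal view."""
        if self.edge_count != 1:
            raise StructuralError("view has more than one edge")
        if self._edges is not None:
            return next(iter(self._edges))
        return next(iter(self.edge_set))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<SubtreeView {self.edge_count} edges, "
                f"{self.leaf_count} leaves>")


# ----------------------------------------------------------------------
# operations on views
# ----------------------------------------------------------------------

def find_centroid(view: SubtreeView) -> int:
    """Centroid of a view: internal node whose removal splits the view into
    components each holding at most ceil(L/2) of its L leaves.

    Among qualifying nodes the one minimising the maximum component leaf
    count is returned, remaining ties broken by smallest node id.
    """
    if view.edge_count < 2:
        raise StructuralError("already terminal: view has a single edge")
    top = view.backbone
    if view.is_fast:
        ws = top._workspace()
        ws.sync_blocked(view._blocked)
        token = ws.next_token()
        c, _, _, _ = centroid_scan(
            top._nbr, top._deg, ws.blocked, view._anchor, ws.visit,
            token, ws.stack, ws.order, ws.parent, ws.leafcnt)
        view._scan_token = token
        if c < 0:  # pragma: no cover - cannot happen on >= 2 edges
            raise StructuralError("no internal node in view")
        return int(c)
    # generic backend over an explicit edge set
    adj = view._explicit_adjacency()
    leaf_nodes = {int(v) for v in view.leaf_nodes}
    total = len(leaf_nodes)
    root = next(iter(adj))
    order: list[int] = []
    parent: dict[int, int] = {root: -1}
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for u in adj[v]:
            if u != parent[v]:
                parent[u] = v
                stack.append(u)
    below = {v: (1 if v in leaf_nodes else 0) for v in adj}
    for v in reversed(order[1:]):
        below[parent[v]] += below[v]
    best, best_max = -1, math.inf
    for v in sorted(adj):
        if len(adj[v]) < 2:
            continue
        mx = 0
        for u in adj[v]:
            c = (total - below[v]) if u == parent[v] else below[u]
            mx = max(mx, c)
        if mx < best_max:
            best, best_max = v, mx
    return best


def decompose(view: SubtreeView, centroid: int) -> tuple[SubtreeView, SubtreeView, SubtreeView]:
    """Split a view into the three parts induced by removing its centroid.

    The centroid's edges stay with the part on their far side, so the three
    edge sets partition the view's edge set.  Parts are ordered by ascending
    backbone-neighbour id.  A backbone direction holding no view edges
    yields an empty part whose covering component records where orienting
    leaves may be drawn from instead.
    """
    top = view.backbone
    if top.degree(centroid) != 3:
        raise StructuralError(f"node {centroid} is not internal")
    nbrs = sorted(top.neighbors(centroid))
    if view.is_fast:
        # membership check: centroid must lie in the anchored component
        # (reuse the visit marks of find_centroid's scan when still fresh)
        ws = top._workspace()
        ws.sync_blocked(view._blocked)
        token = view._scan_token
        if token != ws.token:
            token = ws.next_token()
            component_scan(top._nbr, top._deg, ws.blocked, -1, view._anchor,
                           ws.visit, token, ws.stack, ws.leafbuf)
        if ws.visit[centroid] != token or centroid in view._blocked:
            raise StructuralError(f"centroid {centroid} not in view")
        blocked = view._blocked + (centroid,)
        parts = []
        for u in nbrs:
            cover = (u, centroid)
            if top.is_leaf(u) or u in view._blocked:
                parts.append(SubtreeView(top, edges=frozenset({_edge(centroid, u)}),
                                         cover=cover))
            else:
                parts.append(SubtreeView(top, anchor=u, blocked=blocked, cover=cover))
        return tuple(parts)
    # generic backend
    edges = view._edges
    adj = view._explicit_adjacency()
    if centroid not in adj:
        raise StructuralError(f"centroid {centroid} not in view")
    parts = []
    for u in nbrs:
        cover = (u, centroid)
        if _edge(centroid, u) not in edges:
            parts.append(SubtreeView(top, edges=frozenset(), cover=cover))
            continue
        part_edges = {_edge(centroid, u)}
        seen = {centroid, u}
        stack = [u]
        while stack:
            v = stack.pop()
            for w in adj.get(v, ()):
                if w == centroid and v == u:
                    continue
                e = _edge(v, w)
                if e in edges and e not in part_edges:
                    part_edges.add(e)
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        parts.append(SubtreeView(top, edges=frozenset(part_edges), cover=cover))
    return tuple(parts)


def sample_leaves(view: SubtreeView, count: int, rng: np.random.Generator) -> list[str]:
    """Uniform sample (without replacement) of up to ``count`` taxon names
    from the view's leaves, falling back to the covering backbone component
    when the view has no leaves of its own.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    nodes = view.leaf_nodes
    if len(nodes) == 0:
        nodes = view.covering_leaf_nodes
        if nodes is None or len(nodes) == 0:
            raise StructuralError("view has no leaves and no covering component")
    k = min(count, len(nodes))
    if k == len(nodes):
        picked = nodes
    else:
        idx = rng.choice(len(nodes), size=k, replace=False)
        picked = nodes[np.sort(idx)]
    lab = view.backbone.leaf_label
    return [lab(int(v)) for v in picked]


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------

_NEWICK_UNSAFE = set("()[]{}/\\,;:=*'\"`+<> \t\n")


def _format_label(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(top: Topology, branch_lengths: dict[Edge, float] | None = None) -> str:
    """Serialise a topology to Newick with a canonical child order.

    The tree is written rooted at the internal node adjacent to the leaf
    with the smallest label; at every level children are ordered by their
    smallest descendant label, which makes the output reproducible and
    round-trip stable.  Branch lengths are included only when given.
    """
    ref = min(top.leaves())
    ref_node = top.leaf_node(ref)
    (root,) = top.neighbors(ref_node)

    # iterative post-order: min descendant label and newick fragment per
    # directed edge (parent -> child)
    minlab: dict[int, str] = {}
    frag: dict[int, str] = {}
    stack: list[tuple[int, int, bool]] = [(root, -1, False)]
    while stack:
        v, par, done = stack.pop()
        if top.is_leaf(v):
            minlab[v] = top.leaf_label(v)
            frag[v] = _format_label(top.leaf_label(v))
            continue
        kids = [u for u in top.neighbors(v) if u != par]
        if not done:
            stack.append((v, par, True))
            for u in kids:
                stack.append((u, v, False))
        else:
            kids.sort(key=lambda u: minlab[u])
            minlab[v] = min(minlab[u] for u in kids)
            pieces = []
            for u in kids:
                s = frag[u]
                if branch_lengths is not None:
                    s += f":{branch_lengths[_edge(v, u)]:.10g}"
                pieces.append(s)
            frag[v] = "(" + ",".join(pieces) + ")"
    # root has 3 children (ref + two subtrees); emit as a trifurcation
    kids = sorted(top.neighbors(root), key=lambda u: minlab[u])
    pieces = []
    for u in kids:
        s = frag[u]
        if branch_lengths is not None:
            s += f":{branch_lengths[_edge(root, u)]:.10g}"
        pieces.append(s)
    return "(" + ",".join(pieces) + ");"


def from_newick(source: str, *, with_lengths: bool = False):
    """Parse a Newick string into a :class:`Topology`.

    Branch lengths are ignored unless ``with_lengths`` is set, in which case
    ``(topology, lengths)`` is returned with ``lengths`` keyed by canonical
    edge.  Degree-2 nodes (rooted inputs) are suppressed; multifurcations
    beyond a trifurcating root are rejected, as the container is strictly
    bifurcating.
    """
    import dendropy

    dtree = dendropy.Tree.get(data=source, schema="newick",
                              preserve_underscores=True)
    dtree.suppress_unifurcations()
    if len(dtree.seed_node.child_nodes()) == 2:
        # rooted input: merge the basal bifurcation into a single edge
        dtree.collapse_basal_bifurcation()

    def deg_of(nd) -> int:
        d = len(nd.child_nodes())
        if nd.parent_node is not None:
            d += 1
        return d

    top = Topology()
    lengths: dict[Edge, float] = {}
    node_id: dict[int, int] = {}
    for nd in dtree.preorder_node_iter():
        d = deg_of(nd)
        if d not in (1, 3) and not (nd.parent_node is None and d == 0):
            raise ValueError("multifurcating Newick input; this container is "
                             "strictly bifurcating")
        node_id[id(nd)] = top._new_node()
        if nd.parent_node is not None:
            u, v = node_id[id(nd.parent_node)], node_id[id(nd)]
            top._link(u, v)
            lengths[_edge(u, v)] = float(nd.edge.length or 0.0)
        if d <= 1:
            taxon = nd.taxon.label if nd.taxon is not None else None
            if not taxon:
                raise ValueError("unlabelled leaf in Newick input")
            top._set_leaf(node_id[id(nd)], taxon)

    top.validate()
    if with_lengths:
        return top, lengths
    return top
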