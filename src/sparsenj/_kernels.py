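"""Numba-compiled traversal kernels for array-backed trees.

These implement the hot inner loops of the centroid recursion: component
discovery, leaf collection and centroid selection over a connected region of
the backbone delimited by "blocked" nodes (the centroids removed so far).
Removing a centroid conceptually removes the node but not its edges, so a
region is the set of backbone edges incident to a connected component of
unblocked nodes.

All kernels share the same scratch-array protocol: `visit` holds the last
visit token per node, so a traversal marks nodes by writing the current
`token` instead of clearing a boolean array (O(component) instead of
O(capacity) per call).
"""

from __future__ import annotations

import numba as nb
import numpy as np

__all__ = ["centroid_scan", "component_scan"]


@nb.njit(cache=True)
def centroid_scan(nbr, deg, blocked, anchor, visit, token, stack, order, parent, leafcnt):
    """Find the centroid of the region anchored at `anchor`.

    The region is the component of unblocked nodes reachable from `anchor`
    plus all backbone edges incident to it.  Leaves of the region are
    backbone leaves (degree 1) inside the component; blocked boundary nodes
    are not leaves.  The centroid is the internal node minimising the
    maximum per-component leaf count after its removal, ties broken by
    smallest node id.

    Returns (centroid, n_leaves, n_edges, comp_size); centroid is -1 when
    the component contains no internal node.
    """
    # --- DFS: component membership, parent pointers, order ---------------
    comp_size = 0
    n_leaves = 0
    deg_sum = 0
    top = 0
    stack[0] = anchor
    visit[anchor] = token
    parent[anchor] = -1
    while top >= 0:
        v = stack[top]
        top -= 1
        order[comp_size] = v
        comp_size += 1
        d = deg[v]
        deg_sum += d
        if d == 1:
            n_leaves += 1
        for s in range(3):
            u = nbr[v, s]
            if u >= 0 and blocked[u] == 0 and visit[u] != token:
                visit[u] = token
                parent[u] = v
                top += 1
                stack[top] = u
    # edges incident to the component: internal edges counted twice in the
    # degree sum, boundary edges once; a tree component has comp_size-1
    # internal edges.
    n_edges = deg_sum - (comp_size - 1)

    # --- leaf counts below each node (reverse DFS order is child-first) --
    for i in range(comp_size):
        v = order[i]
        leafcnt[v] = 1 if deg[v] == 1 else 0
    for i in range(comp_size - 1, 0, -1):
        v = order[i]
        leafcnt[parent[v]] += leafcnt[v]

    # --- centroid: argmin over internal nodes of max component leaves ----
    best = -1
    best_max = np.int64(2**62)
    for i in range(comp_size):
        v = order[i]
        if deg[v] < 2:
            continue
        mx = 0
        for s in range(3):
            u = nbr[v, s]
            if u < 0:
                continue
            if blocked[u] != 0:
                c = 0  # boundary edge: no region leaves behind it
            elif u == parent[v]:
                c = n_leaves - leafcnt[v]
            else:
                c = leafcnt[u]
            if c > mx:
                mx = c
        if mx < best_max or (mx == best_max and (best == -1 or v < best)):
            best_max = mx
            best = v
    return best, n_leaves, n_edges, comp_size


@nb.njit(cache=True)
def component_scan(nbr, deg, blocked, extra_block, anchor, visit, token, stack, leaves_out):
    """Collect stats and leaf ids of the region anchored at `anchor`.

    Avoids nodes with `blocked` set and the single node `extra_block`
    (pass -1 for none).  Leaf node ids are written to `leaves_out` in
    deterministic DFS order.  Returns (n_leaves, n_edges, comp_size).
    """
    comp_size = 0
    n_leaves = 0
    deg_sum = 0
    top = 0
    stack[0] = anchor
    visit[anchor] = token
    while top >= 0:
        v = stack[top]
        top -= 1
        comp_size += 1
        d = deg[v]
        deg_sum += d
        if d == 1:
            leaves_out[n_leaves] = v
            n_leaves += 1
        for s in range(3):
            u = nbr[v, s]
            if u >= 0 and u != extra_block and blocked[u] == 0 and visit[u] != token:
                visit[u] = token
                top += 1
                stack[top] = u
    n_edges = deg_sum - (comp_size - 1)
    return n_leaves, n_edges, comp_size
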