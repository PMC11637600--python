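"""Topology structure, centroid decomposition, leaf insertion, Newick I/O."""

import math

import numpy as np
import pytest

from helpers import all_topologies, caterpillar, splits_of
from sparsenj.simulate import random_topology
from sparsenj.tree import (StructuralError, SubtreeView, Topology, decompose,
                           find_centroid, from_newick, sample_leaves,
                           to_newick)


def _component_leaf_counts(view, centroid):
    """Leaf counts of the parts a centroid induces (empty parts -> 0)."""
    return [p.leaf_count for p in decompose(view, centroid)]


class TestTopologyStructure:
    def test_counts_and_degrees_after_growth(self):
        rng = np.random.default_rng(0)
        top = Topology.quartet(("a", "b"), ("c", "d"))
        labels = [f"x{i}" for i in range(30)]
        for lab in labels:
            edges = top.edges()
            top.insert_leaf(edges[int(rng.integers(len(edges)))], lab)
            top.validate()
        k = top.n_leaves
        assert (k, top.n_nodes, top.n_edges) == (34, 2 * k - 2, 2 * k - 3)

    def test_insert_on_each_quartet_edge_gives_distinct_topologies(self):
        base = Topology.quartet(("a", "b"), ("c", "d"))
        seen = set()
        for e in base.edges():
            t = base.copy()
            t.insert_leaf(e, "e")
            t.validate()
            seen.add(splits_of(t))
        assert len(seen) == 5

    def test_insert_errors(self):
        top = Topology.quartet(("a", "b"), ("c", "d"))
        with pytest.raises(ValueError, match="duplicate"):
            top.insert_leaf(top.edges()[0], "a")
        with pytest.raises(StructuralError):
            top.insert_leaf((97, 98), "z")

    def test_insert_remove_identity_on_splits(self):
        rng = np.random.default_rng(1)
        top = random_topology(10, rng)
        before = splits_of(top)
        edge = top.remove_leaf("t5")
        back = top.insert_leaf(edge, "t5")
        assert top.is_leaf(back)
        assert splits_of(top) == before

    def test_reinsertion_edge_is_unique_against_true_splits(self):
        # inserting on the correct edge (and only that edge) reproduces
        # the true (k+1)-leaf split set
        rng = np.random.default_rng(2)
        truth = random_topology(9, rng)
        target = splits_of(truth)
        pruned = truth.copy()
        merged = pruned.remove_leaf("t4")
        matching = []
        for e in pruned.edges():
            t = pruned.copy()
            t.insert_leaf(e, "t4")
            if splits_of(t) == target:
                matching.append(e)
        assert matching == [tuple(sorted(merged))]


class TestCentroid:
    def test_quartet_centroid_deterministic_and_balanced(self):
        top = Topology.quartet(("a", "b"), ("c", "d"))
        view = SubtreeView.whole(top)
        c = find_centroid(view)
        internals = top.internal_nodes()
        assert c == min(internals)  # both qualify; smallest id wins
        assert max(_component_leaf_counts(view, c)) <= 2

    def test_caterpillar_centroid_matches_bruteforce(self):
        top = caterpillar([f"a{i}" for i in range(8)])
        view = SubtreeView.whole(top)
        c = find_centroid(view)
        best = min(
            ((max(_component_leaf_counts(view, v)), v)
             for v in top.internal_nodes()))
        assert (max(_component_leaf_counts(view, c)), c) == best

    def test_centroid_bound_on_random_topologies(self):
        # every component after centroid removal has <= ceil(L/2) leaves
        rng = np.random.default_rng(3)
        for _ in range(400):
            n = int(rng.integers(4, 201))
            top = random_topology(n, rng)
            view = SubtreeView.whole(top)
            c = find_centroid(view)
            counts = _component_leaf_counts(view, c)
            assert max(counts) <= math.ceil(n / 2)
            assert sum(counts) == n

    def test_single_edge_view_is_terminal(self):
        top = Topology.quartet(("a", "b"), ("c", "d"))
        e = top.edges()[0]
        view = SubtreeView.from_edges(top, [e])
        with pytest.raises(StructuralError, match="terminal"):
            find_centroid(view)

    def test_disconnected_view_rejected(self):
        top = caterpillar([f"a{i}" for i in range(6)])
        la, lb = top.leaf_node("a0"), top.leaf_node("a5")
        ea = (la, top.neighbors(la)[0])
        eb = (lb, top.neighbors(lb)[0])
        view = SubtreeView.from_edges(top, [ea, eb])
        with pytest.raises(StructuralError, match="disconnected"):
            find_centroid(view)

    def test_recursion_depth_descending_largest_part(self):
        for n in (16, 64, 150):
            top = caterpillar([f"a{i:03d}" for i in range(n)])
            view = SubtreeView.whole(top)
            steps = 0
            while view.edge_count > 1:
                c = find_centroid(view)
                parts = decompose(view, c)
                view = max(parts, key=lambda p: (p.edge_count, p.leaf_count))
                steps += 1
            assert steps <= math.ceil(math.log2(2 * n - 3)) + 2


class TestDecompose:
    def test_quartet_part_edge_counts(self):
        top = Topology.quartet(("a", "b"), ("c", "d"))
        view = SubtreeView.whole(top)
        c = find_centroid(view)
        sizes = sorted(p.edge_count for p in decompose(view, c))
        assert sizes == [1, 1, 3]

    def test_parts_partition_view_edges(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            top = random_topology(int(rng.integers(5, 40)), rng)
            view = SubtreeView.whole(top)
            c = find_centroid(view)
            parts = decompose(view, c)
            union = set()
            total = 0
            for p in parts:
                es = p.edge_set
                total += len(es)
                union |= es
            assert union == view.edge_set
            assert total == view.edge_count

    def test_centroid_not_in_view_rejected(self):
        top = caterpillar([f"a{i}" for i in range(8)])
        leaf = top.leaf_node("a0")
        hub = top.neighbors(leaf)[0]
        nxt = next(u for u in top.neighbors(hub)
                   if u != leaf and not top.is_leaf(u))
        view = SubtreeView.from_edges(
            top, [tuple(sorted((leaf, hub))), tuple(sorted((hub, nxt)))])
        view_nodes = {x for e in view.edge_set for x in e}
        outside = next(v for v in top.internal_nodes() if v not in view_nodes)
        with pytest.raises(StructuralError):
            decompose(view, outside)

    def test_boundary_centroid_yields_empty_part_with_cover(self):
        # 2-edge view on a 6-leaf backbone: the middle node has backbone
        # degree 3 but view degree 2, so one part is empty and covered by
        # the backbone component behind the third direction
        top = caterpillar([f"a{i}" for i in range(6)])
        spine = [v for v in top.internal_nodes()]
        # pick an internal node with two internal neighbours
        mid = next(v for v in spine
                   if sum(not top.is_leaf(u) for u in top.neighbors(v)) == 2)
        u, w = [x for x in top.neighbors(mid) if not top.is_leaf(x)]
        view = SubtreeView.from_edges(
            top, [tuple(sorted((mid, u))), tuple(sorted((mid, w)))])
        c = find_centroid(view)
        assert c == mid
        parts = decompose(view, c)
        empties = [p for p in parts if p.edge_count == 0]
        assert len(empties) == 1
        cover = empties[0].covering_leaf_nodes
        # the cover is exactly the backbone component behind mid's leaf
        leaf_dir = next(x for x in top.neighbors(mid) if top.is_leaf(x))
        assert [int(v) for v in cover] == [leaf_dir]

    def test_backends_agree_along_the_recursion(self):
        # the compact anchored representation and the explicit edge-set
        # backend must return identical centroids and partitions
        rng = np.random.default_rng(5)
        for _ in range(15):
            top = random_topology(int(rng.integers(6, 60)), rng)
            fast = SubtreeView.whole(top)
            while fast.edge_count > 1:
                explicit = SubtreeView.from_edges(top, fast.edge_set)
                cf = find_centroid(fast)
                ce = find_centroid(explicit)
                assert cf == ce
                pf = decompose(fast, cf)
                pe = decompose(explicit, ce)
                for a, b in zip(pf, pe):
                    assert a.edge_set == b.edge_set
                    assert a.leaf_set == b.leaf_set
                fast = max(pf, key=lambda p: p.edge_count)


class TestSampleLeaves:
    def test_truncation_to_single_leaf(self):
        top = Topology.quartet(("a", "b"), ("c", "d"))
        leaf = top.leaf_node("a")
        view = SubtreeView.from_edges(top, [(leaf, top.neighbors(leaf)[0])])
        out = sample_leaves(view, 5, np.random.default_rng(0))
        assert out == ["a"]

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        top = random_topology(30, rng)
        view = SubtreeView.whole(top)
        s1 = sample_leaves(view, 5, np.random.default_rng(123))
        s2 = sample_leaves(view, 5, np.random.default_rng(123))
        assert s1 == s2
        assert len(set(s1)) == 5

    def test_empty_part_samples_from_cover(self):
        top = caterpillar([f"a{i}" for i in range(6)])
        mid = next(v for v in top.internal_nodes()
                   if sum(not top.is_leaf(u) for u in top.neighbors(v)) == 2)
        u, w = [x for x in top.neighbors(mid) if not top.is_leaf(x)]
        view = SubtreeView.from_edges(
            top, [tuple(sorted((mid, u))), tuple(sorted((mid, w)))])
        empty = next(p for p in decompose(view, mid) if p.edge_count == 0)
        out = sample_leaves(empty, 1, np.random.default_rng(0))
        leaf_dir = next(x for x in top.neighbors(mid) if top.is_leaf(x))
        assert out == [top.leaf_label(leaf_dir)]

    def test_no_leaves_anywhere_raises(self):
        top = Topology.quartet(("a", "b"), ("c", "d"))
        view = SubtreeView(top, edges=frozenset())
        with pytest.raises((StructuralError, ValueError)):
            sample_leaves(view, 1, np.random.default_rng(0))


class TestNewick:
    def test_roundtrip_byte_identical(self):
        rng = np.random.default_rng(7)
        top = random_topology(25, rng)
        s1 = to_newick(top)
        s2 = to_newick(from_newick(s1))
        assert s1 == s2

    def test_roundtrip_preserves_splits(self):
        rng = np.random.default_rng(8)
        top = random_topology(40, rng)
        assert splits_of(from_newick(to_newick(top))) == splits_of(top)

    def test_dendropy_agrees_on_splits(self):
        import dendropy

        rng = np.random.default_rng(9)
        top = random_topology(12, rng)
        s = to_newick(top)
        dt = dendropy.Tree.get(data=s, schema="newick")
        d_splits = set()
        taxa = sorted(t.label for t in dt.taxon_namespace)
        dt.encode_bipartitions()
        for bp in dt.bipartition_encoding:
            mask = bp.leafset_bitmask
            side = frozenset(t.label for i, t in enumerate(dt.taxon_namespace)
                             if mask & (1 << i))
            if min(taxa) in side:
                side = frozenset(taxa) - side
            if 2 <= len(side) <= len(taxa) - 2:
                d_splits.add(side)
        assert d_splits == set(splits_of(top))

    def test_rooted_input_unrooted_on_read(self):
        top = from_newick("((a:1,b:2):0.5,(c:1,d:1):0.5);")
        top.validate()
        assert top.n_leaves == 4

    def test_quoted_labels_roundtrip(self):
        top = Topology.quartet(("sp one", "b"), ("c(x)", "d"))
        s = to_newick(top)
        back = from_newick(s)
        assert set(back.leaves()) == {"sp one", "b", "c(x)", "d"}

    def test_multifurcation_rejected(self):
        with pytest.raises(ValueError, match="multifurcating"):
            from_newick("((a,b,c,d),(e,f));")

    def test_branch_lengths_roundtrip(self):
        src = "((a:0.1,b:0.2):0.05,c:0.3,d:0.4);"
        top, lengths = from_newick(src, with_lengths=True)
        total = sum(lengths.values())
        assert total == pytest.approx(1.05)

    def test_exhaustive_five_leaf_topologies_distinct_newick(self):
        trees = all_topologies(["a", "b", "c", "d", "e"])
        assert len(trees) == 15
        assert len({to_newick(t) for t in trees}) == 15
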