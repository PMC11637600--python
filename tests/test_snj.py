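"""Sparse NJ: backbone construction, quartet steering, full inference."""

import itertools
import math

import numpy as np
import pytest

from helpers import brute_rf, random_weighted, splits_of
from sparsenj.distances import TreeDistanceOracle
from sparsenj.nj import neighbor_joining
from sparsenj.snj import (SNJConfig, build_quartet_matrix, initial_backbone,
                          place_leaf, run_snj, select_subtree)
from sparsenj.tree import to_newick


class TestConfig:
    def test_k0_auto_enhanced(self):
        cfg = SNJConfig(mode="enhanced")
        assert cfg.resolved_k0(1000) == math.ceil(math.sqrt(1000 * math.log2(1000)))
        assert cfg.resolved_k0(4) == 4  # clamped to n

    def test_sampling_defaults(self):
        assert SNJConfig(mode="basic").resolved_sampling(1000) == (1, 1)
        assert SNJConfig(mode="enhanced").resolved_sampling(1000) == (10, 3)

    def test_orienting_cannot_exceed_samples(self):
        cfg = SNJConfig(mode="enhanced", samples_per_subtree=2,
                        orienting_per_subtree=3)
        with pytest.raises(ValueError, match="exceed"):
            cfg.resolved_sampling(100)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            SNJConfig(mode="fancy")


class TestInitialBackbone:
    def test_n4_backbone_is_nj_quartet_with_empty_remainder(self):
        rng = np.random.default_rng(0)
        wt = random_weighted(4, rng)
        o = TreeDistanceOracle(wt)
        backbone, rest = initial_backbone(
            wt.topology.leaves(), o, SNJConfig(mode="basic"),
            np.random.default_rng(1))
        assert rest == []
        assert splits_of(backbone) == splits_of(
            neighbor_joining(TreeDistanceOracle(wt)))

    def test_query_count_is_k0_choose_2(self):
        rng = np.random.default_rng(1)
        wt = random_weighted(40, rng)
        o = TreeDistanceOracle(wt)
        initial_backbone(wt.topology.leaves(), o,
                         SNJConfig(mode="enhanced", k0=10),
                         np.random.default_rng(2))
        assert o.distinct_query_count == 45

    def test_fixed_seed_reproducible(self):
        rng_tree = np.random.default_rng(2)
        wt = random_weighted(30, rng_tree)
        outs = []
        for _ in range(2):
            o = TreeDistanceOracle(wt)
            b, rest = initial_backbone(
                wt.topology.leaves(), o, SNJConfig(mode="enhanced", seed=3),
                np.random.default_rng(77), np.random.default_rng(78))
            outs.append((to_newick(b), tuple(rest)))
        assert outs[0] == outs[1]


class TestQuartetMatrix:
    def test_singletons_reduce_to_plain_matrix(self):
        rng = np.random.default_rng(3)
        wt = random_weighted(8, rng)
        o = TreeDistanceOracle(wt)
        taxa = wt.topology.leaves()
        l, a, b, c = taxa[:4]
        D = build_quartet_matrix(l, [[a], [b], [c]], o)
        assert D[0, 1] == o.query(l, a)
        assert D[2, 3] == o.query(b, c)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_averaging_matches_literal_means(self):
        rng = np.random.default_rng(4)
        wt = random_weighted(12, rng)
        o = TreeDistanceOracle(wt)
        taxa = wt.topology.leaves()
        l = taxa[0]
        sets = [taxa[1:4], taxa[4:7], taxa[7:10]]
        D = build_quartet_matrix(l, sets, o)
        for i in range(3):
            assert D[0, i + 1] == pytest.approx(
                np.mean([o.query(l, x) for x in sets[i]]))
        for i, j in itertools.combinations(range(3), 2):
            expect = np.mean([o.query(x, y)
                              for x in sets[i] for y in sets[j]])
            assert D[i + 1, j + 1] == pytest.approx(expect)

    def test_empty_set_rejected(self):
        rng = np.random.default_rng(5)
        wt = random_weighted(6, rng)
        o = TreeDistanceOracle(wt)
        taxa = wt.topology.leaves()
        with pytest.raises(ValueError, match="non-empty"):
            build_quartet_matrix(taxa[0], [[taxa[1]], [], [taxa[2]]], o)


class TestSelectSubtree:
    @pytest.mark.parametrize("split,expected", [
        ((("a", "l"), ("b", "c")), 0),
        ((("b", "l"), ("a", "c")), 1),
        ((("c", "l"), ("a", "b")), 2),
        ((("a", "b"), ("l", "c")), 2),
    ])
    def test_partner_maps_to_part(self, split, expected):
        assert select_subtree(split) == expected


class TestPlaceLeaf:
    def test_noiseless_returns_true_attachment_edge(self):
        rng = np.random.default_rng(6)
        for mode in ("basic", "enhanced"):
            for _ in range(10):
                n = int(rng.integers(6, 31))
                wt = random_weighted(n, rng)
                o = TreeDistanceOracle(wt)
                taxa = wt.topology.leaves()
                drop = taxa[int(rng.integers(n))]
                backbone = wt.topology.copy()
                merged = backbone.remove_leaf(drop)
                edge = place_leaf(backbone, drop, o,
                                  SNJConfig(mode=mode, seed=0),
                                  np.random.default_rng(1))
                assert tuple(sorted(edge)) == tuple(sorted(merged))

    def test_three_leaf_backbone_single_round(self):
        rng = np.random.default_rng(7)
        wt = random_weighted(4, rng)
        backbone = wt.topology.copy()
        taxa = wt.topology.leaves()
        backbone.remove_leaf(taxa[0])
        o = TreeDistanceOracle(wt)
        rounds = []
        place_leaf(backbone, taxa[0], o, SNJConfig(mode="basic"),
                   np.random.default_rng(2), rounds_out=rounds)
        assert rounds == [1]

    def test_rounds_and_queries_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = int(rng.integers(20, 120))
            wt = random_weighted(n, rng)
            o = TreeDistanceOracle(wt)
            taxa = wt.topology.leaves()
            drop = taxa[0]
            backbone = wt.topology.copy()
            backbone.remove_leaf(drop)
            k = backbone.n_leaves
            cfg = SNJConfig(mode="enhanced", seed=0)
            samples, _ = cfg.resolved_sampling(n)
            before = o.distinct_query_count
            rounds = []
            place_leaf(backbone, drop, o, cfg, np.random.default_rng(3),
                       n_total=n, rounds_out=rounds)
            bound_rounds = math.ceil(math.log2(2 * k - 3)) + 2
            assert rounds[0] <= bound_rounds
            # per round: 3*samples new-taxon distances plus at most 27
            # cross distances
            assert (o.distinct_query_count - before
                    <= (3 * samples + 27) * bound_rounds)


class TestRunSNJ:
    def test_n4_equals_dense_nj(self):
        rng = np.random.default_rng(9)
        wt = random_weighted(4, rng)
        est = run_snj(wt.topology.leaves(), TreeDistanceOracle(wt),
                      SNJConfig(mode="basic", seed=0))
        assert splits_of(est) == splits_of(
            neighbor_joining(TreeDistanceOracle(wt)))

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_noiseless_recovery(self, n):
        rng = np.random.default_rng(n)
        wt = random_weighted(n, rng)
        for mode in ("basic", "enhanced"):
            est = run_snj(wt.topology.leaves(), TreeDistanceOracle(wt),
                          SNJConfig(mode=mode, seed=n))
            assert brute_rf(wt.topology, est) == 0.0

    def test_fixed_seed_byte_identical(self):
        rng = np.random.default_rng(10)
        wt = random_weighted(40, rng)
        outs = {to_newick(run_snj(wt.topology.leaves(),
                                  TreeDistanceOracle(wt),
                                  SNJConfig(mode="enhanced", seed=12)))
                for _ in range(2)}
        assert len(outs) == 1

    def test_basic_total_query_bound(self):
        # the basic variant touches at most ~3 n log2 n distinct pairs
        # (3 new-taxon distances per quartet round, cross pairs heavily
        # cached) plus the 6 initial-quartet entries
        n = 1000
        rng = np.random.default_rng(11)
        wt = random_weighted(n, rng)
        o = TreeDistanceOracle(wt)
        run_snj(wt.topology.leaves(), o, SNJConfig(mode="basic", seed=0))
        assert o.distinct_query_count <= 3 * n * math.log2(n) + 6

    def test_query_fraction_decreases_with_n(self):
        fracs = []
        for n in (250, 500, 1000):
            rng = np.random.default_rng(n)
            wt = random_weighted(n, rng)
            o = TreeDistanceOracle(wt)
            stats = {}
            run_snj(wt.topology.leaves(), o,
                    SNJConfig(mode="enhanced", seed=1), stats_out=stats)
            fracs.append(stats["query_fraction"])
        assert fracs[0] > fracs[1] > fracs[2]

    def test_too_few_taxa(self):
        rng = np.random.default_rng(12)
        wt = random_weighted(4, rng)
        with pytest.raises(ValueError):
            run_snj(wt.topology.leaves()[:3], TreeDistanceOracle(wt),
                    SNJConfig())
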