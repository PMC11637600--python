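"""Sparse Neighbor Joining: incremental topology inference with a sparse
set of distance queries.

Instead of computing the dense distance matrix, the method builds a small
initial backbone with dense NJ and then inserts the remaining taxa one at a
time.  Each insertion walks down the backbone by centroid decomposition: the
current subtree is split at its centroid into three parts, one orienting
leaf (or an averaged set of them) represents each part, and a 4-taxon NJ
quartet with the new taxon decides which part to descend into.  The walk
halves the subtree each round, so an insertion needs O(log n) quartets and
the whole run touches O(n log n) distance entries in the basic variant and
O(n log^2 n) in the enhanced one.

Two variants:

* ``basic`` — 4-leaf initial backbone, one uniformly sampled orienting leaf
  per part;
* ``enhanced`` — backbone of k0 = ceil(sqrt(n log2 n)) leaves, ceil(log2 n)
  sampled candidates per part of which the 3 closest to the new taxon (by
  oracle distance) become the orienting set, with quartet entries averaged
  over the sets.

Parts that contain no leaves of their own borrow orienting leaves from the
backbone component that covers them.  All randomness flows from one master
seed through three named substreams (backbone choice, insertion order,
per-insertion sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distances import DistanceOracle
from .nj import neighbor_joining, quartet_topology
from .tree import (Edge, StructuralError, SubtreeView, Topology, decompose,
                   find_centroid, sample_leaves)

__all__ = [
    "SNJConfig",
    "initial_backbone",
    "build_quartet_matrix",
    "select_subtree",
    "place_leaf",
    "run_snj",
]

_QUARTET_NAMES = ("l", "a", "b", "c")


@dataclass
class SNJConfig:
    """Tunable parameters of a sparse inference run.

    ``None`` fields resolve from the problem size n at run time:
    k0 = 4 (basic) or max(4, ceil(sqrt(n log2 n))) clamped to n (enhanced);
    samples_per_subtree = 1 (basic) or ceil(log2 n) (enhanced);
    orienting_per_subtree = 1 (basic) or 3 (enhanced).
    """

    mode: str = "enhanced"
    k0: int | None = None
    samples_per_subtree: int | None = None
    orienting_per_subtree: int | None = None
    seed: int = 0
    insertion_order: str = "shuffle"  # or "given"

    def __post_init__(self) -> None:
        if self.mode not in ("basic", "enhanced"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.insertion_order not in ("shuffle", "given"):
            raise ValueError(f"unknown insertion order {self.insertion_order!r}")

    def resolved_k0(self, n: int) -> int:
        if self.k0 is not None:
            k0 = self.k0
        elif self.mode == "basic":
            k0 = 4
        else:
            k0 = max(4, math.ceil(math.sqrt(n * math.log2(n))))
        k0 = min(k0, n)
        if k0 < 4:
            raise ValueError("k0 must be at least 4")
        return k0

    def resolved_sampling(self, n: int) -> tuple[int, int]:
        """(samples_per_subtree, orienting_per_subtree) for n total taxa."""
        if self.mode == "basic":
            samples = self.samples_per_subtree or 1
            orienting = self.orienting_per_subtree or 1
        else:
            samples = self.samples_per_subtree or max(1, math.ceil(math.log2(n)))
            orienting = self.orienting_per_subtree or 3
        if orienting > samples:
            raise ValueError("orienting_per_subtree cannot exceed "
                             "samples_per_subtree")
        return samples, orienting


def initial_backbone(taxa: Sequence[str], oracle: DistanceOracle,
                     config: SNJConfig, rng: np.random.Generator,
                     order_rng: np.random.Generator | None = None
                     ) -> tuple[Topology, list[str]]:
    """Dense-NJ backbone on k0 uniformly sampled taxa.

    Returns the backbone and the remaining taxa in insertion order
    (shuffled by ``order_rng`` unless the config asks for the given order).
    Consumes exactly k0(k0-1)/2 distinct oracle queries.
    """
    taxa = list(taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    k0 = config.resolved_k0(n)
    idx = rng.choice(n, size=k0, replace=False)
    chosen = set(int(i) for i in idx)
    backbone_taxa = [taxa[i] for i in sorted(chosen)]
    rest = [t for i, t in enumerate(taxa) if i not in chosen]
    if config.insertion_order == "shuffle":
        r = order_rng if order_rng is not None else rng
        r.shuffle(rest)
    backbone = neighbor_joining(oracle, backbone_taxa)
    return backbone, rest


def build_quartet_matrix(new_taxon: str,
                         orienting_sets: Sequence[Sequence[str]],
                         oracle: DistanceOracle) -> np.ndarray:
    """4x4 distance matrix over (new taxon, set A, set B, set C).

    Entries involving the new taxon average d(l, x) over the set; entries
    between two sets average over all cross pairs.  Singleton sets reduce
    to a plain 4-taxon matrix.
    """
    if len(orienting_sets) != 3 or any(len(s) == 0 for s in orienting_sets):
        raise ValueError("need three non-empty orienting sets")
    D = np.zeros((4, 4), dtype=float)
    for i, s in enumerate(orienting_sets, start=1):
        D[0, i] = D[i, 0] = sum(oracle.query(new_taxon, x) for x in s) / len(s)
    for i in range(1, 4):
        for j in range(i + 1, 4):
            si, sj = orienting_sets[i - 1], orienting_sets[j - 1]
            tot = sum(oracle.query(x, y) for x in si for y in sj)
            D[i, j] = D[j, i] = tot / (len(si) * len(sj))
    return D


def select_subtree(split: tuple[tuple[str, str], tuple[str, str]],
                   new_label: str = "l") -> int:
    """Index (0, 1, 2) of the part whose representative is the new taxon's
    cherry partner in the quartet split."""
    for cherry in split:
        if new_label in cherry:
            partner = cherry[0] if cherry[1] == new_label else cherry[1]
            return _QUARTET_NAMES.index(partner) - 1
    raise ValueError("split does not involve the new taxon")


def place_leaf(backbone: Topology, new_taxon: str, oracle: DistanceOracle,
               config: SNJConfig, rng: np.random.Generator, *,
               n_total: int | None = None,
               rounds_out: list[int] | None = None) -> Edge:
    """Choose the backbone edge where the new taxon should be inserted.

    Walks the centroid recursion: split the current subtree at its
    centroid, represent each part by orienting leaves, resolve the quartet
    with the new taxon, descend into the selected part; stops when a single
    edge remains.  The number of quartet rounds is at most
    ceil(log2(2k-3)) + 2 for a k-leaf backbone.
    """
    if backbone.n_leaves < 3:
        raise StructuralError("backbone must have at least 3 leaves")
    if new_taxon in backbone.leaf_labels.values():
        raise ValueError(f"{new_taxon!r} is already in the backbone")
    n = n_total if n_total is not None else backbone.n_leaves + 1
    samples, orienting = config.resolved_sampling(n)

    view = SubtreeView.whole(backbone)
    rounds = 0
    while view.edge_count != 1:
        centroid = find_centroid(view)
        parts = decompose(view, centroid)
        sets = []
        for part in parts:
            cand = sample_leaves(part, samples, rng)
            if len(cand) > orienting:
                ranked = sorted(cand,
                                key=lambda x: (oracle.query(new_taxon, x), x))
                cand = ranked[:orienting]
            sets.append(cand)
        D = build_quartet_matrix(new_taxon, sets, oracle)
        split = quartet_topology(_QUARTET_NAMES, D)
        view = parts[select_subtree(split)]
        rounds += 1
    if rounds_out is not None:
        rounds_out.append(rounds)
    return view.single_edge


def run_snj(taxa: Sequence[str], oracle: DistanceOracle, config: SNJConfig,
            stats_out: dict | None = None) -> Topology:
    """Full sparse inference: initial backbone, then one placement per
    remaining taxon.  Fully reproducible from ``config.seed``."""
    taxa = list(taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    ss = np.random.SeedSequence(config.seed)
    s_backbone, s_order, s_place = ss.spawn(3)
    backbone, rest = initial_backbone(
        taxa, oracle, config, np.random.default_rng(s_backbone),
        order_rng=np.random.default_rng(s_order))
    place_rng = np.random.default_rng(s_place)
    rounds: list[int] = []
    for taxon in rest:
        edge = place_leaf(backbone, taxon, oracle, config, place_rng,
                          n_total=n, rounds_out=rounds)
        backbone.insert_leaf(edge, taxon)
    if stats_out is not None:
        stats_out.update({
            "n": n,
            "k0": config.resolved_k0(n),
            "mode": config.mode,
            "distinct_query_count": oracle.distinct_query_count,
            "total_pairs": oracle.total_pairs,
            "query_fraction": oracle.query_fraction,
            "quartet_rounds_total": int(sum(rounds)),
            "insertions": len(rounds),
        })
    return backbone
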