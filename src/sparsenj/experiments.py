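"""Experiment drivers: simulate -> infer -> compare sweeps and the
per-insertion placement audit.

`experiment_sweep` reproduces the standard benchmark loop — simulate a
random weighted topology and Jukes–Cantor alignment, infer with sparse NJ
(optionally also dense NJ), score against the truth — over a grid of
(n, m, seed) cells, emitting one tidy row per cell.

`insertion_error_audit` measures placement quality per taxon: each inserted
leaf's chosen edge is compared (in edges of tree distance) with the edge
where a reference tree would attach it, and the leaf is then relocated to
its reference position so errors do not propagate to later insertions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import DistanceOracle, SequenceDistanceOracle
from .metrics import compare_trees, edge_displacement
from .nj import neighbor_joining
from .simulate import simulate_dataset
from .snj import SNJConfig, initial_backbone, place_leaf, run_snj
from .tree import Topology

__all__ = ["RunManifest", "experiment_sweep", "insertion_error_audit"]


@dataclass
class RunManifest:
    """Provenance sidecar for an inference run: everything needed to
    reproduce the output tree bit-for-bit."""

    command: str
    config: dict
    seed: int
    versions: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    distinct_query_count: int | None = None
    wall_time_s: float | None = None

    @staticmethod
    def digest(path: str) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()

    def collect_versions(self) -> None:
        import numpy
        import sparsenj
        self.versions = {"sparsenj": sparsenj.__version__,
                         "numpy": numpy.__version__}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _estimate_cell_bytes(n: int, m: int, include_nj: bool) -> int:
    seq_bytes = 2 * n * m          # all node sequences during evolution
    nj_bytes = 8 * n * n if include_nj else 0
    return seq_bytes + nj_bytes


def experiment_sweep(ns: Sequence[int], ms: Sequence[int],
                     seeds: Sequence[int], mode: str = "enhanced",
                     distance: str = "jc", bl_scale: float = 1e-3,
                     include_nj: bool = False,
                     quartet_samples: int = 20_000,
                     memory_cap_bytes: int = 4 << 30) -> pd.DataFrame:
    """Run the simulate -> infer -> compare pipeline over a grid.

    Returns a DataFrame with one row per (n, m, seed) cell.  Deterministic:
    the same grid and seeds give a byte-identical table.  Cells whose
    estimated peak memory exceeds ``memory_cap_bytes`` are refused.
    """
    rows = []
    for n in ns:
        for m in ms:
            est = _estimate_cell_bytes(n, m, include_nj)
            if est > memory_cap_bytes:
                raise MemoryError(
                    f"cell (n={n}, m={m}) estimated at {est/2**30:.1f} GiB "
                    f"exceeds the configured cap")
            for seed in seeds:
                wt, seqs = simulate_dataset(n, m, seed, bl_scale)
                oracle = SequenceDistanceOracle(seqs, model=distance)
                stats: dict = {}
                cfg = SNJConfig(mode=mode, seed=seed)
                tree = run_snj(seqs.taxa, oracle, cfg, stats_out=stats)
                rep = compare_trees(wt.topology, tree,
                                    quartet_mode="auto" if n <= 30 else "sample",
                                    quartet_samples=quartet_samples, seed=seed)
                row = {
                    "n": n, "m": m, "seed": seed, "mode": mode,
                    "rf": rep.rf, "transfer": rep.transfer,
                    "quartet": rep.quartet,
                    "distinct_queries": stats["distinct_query_count"],
                    "total_pairs": stats["total_pairs"],
                    "query_fraction": stats["query_fraction"],
                }
                if include_nj:
                    nj_oracle = SequenceDistanceOracle(seqs, model=distance)
                    nj_tree = neighbor_joining(nj_oracle, seqs.taxa)
                    nj_rep = compare_trees(
                        wt.topology, nj_tree,
                        quartet_mode="auto" if n <= 30 else "sample",
                        quartet_samples=quartet_samples, seed=seed)
                    row.update({"nj_rf": nj_rep.rf,
                                "nj_transfer": nj_rep.transfer,
                                "nj_quartet": nj_rep.quartet})
                rows.append(row)
    return pd.DataFrame(rows)


def _attachment_bipartition(reference: Topology, taxon: str,
                            backbone_taxa: list[str]) -> set[str]:
    """One side of the bipartition of the backbone taxa induced by the
    reference attachment point of ``taxon``.

    The attachment point is where the taxon's path meets the Steiner tree
    of the backbone taxa in the reference: rooted at the taxon's leaf,
    descend while a single subtree holds every backbone taxon; the first
    node where they split in two yields the bipartition.
    """
    wanted = set(backbone_taxa)
    x = reference.leaf_node(taxon)
    parent = {x: -1}
    order = [x]
    stack = [x]
    while stack:
        v = stack.pop()
        for u in reference.neighbors(v):
            if u != parent[v]:
                parent[u] = v
                order.append(u)
                stack.append(u)
    below: dict[int, set[str]] = {}
    for v in reversed(order):
        s = set()
        if reference.is_leaf(v) and reference.leaf_label(v) in wanted:
            s.add(reference.leaf_label(v))
        for u in reference.neighbors(v):
            if u != parent[v]:
                s |= below[u]
        below[v] = s
    v = x
    while True:
        kids = [u for u in reference.neighbors(v) if u != parent[v]]
        carriers = [u for u in kids if below[u]]
        if len(carriers) != 1:
            break  # backbone taxa split here (or v is their closest point)
        v = carriers[0]
    # at the split point, each carrier subtree is one side
    return set(below[carriers[0]])


def _reference_attachment_edge(backbone: Topology, taxon: str,
                               reference: Topology):
    """The backbone edge where ``taxon`` attaches according to the
    reference tree: the edge whose bipartition of the backbone taxa needs
    the fewest side-switches to match the reference attachment
    bipartition (exact when backbone and reference agree); ties broken by
    smallest edge."""
    taxa = sorted(backbone.leaf_labels.values())
    n = len(taxa)
    tindex = {t: i for i, t in enumerate(taxa)}
    side = _attachment_bipartition(reference, taxon, taxa)
    target = 0
    for t in side:
        target |= 1 << tindex[t]
    # per-edge bipartition masks of the backbone, rooted at taxa[0]'s leaf
    root = backbone.leaf_node(taxa[0])
    parent = {root: -1}
    order = [root]
    stack = [root]
    while stack:
        v = stack.pop()
        for u in backbone.neighbors(v):
            if u != parent[v]:
                parent[u] = v
                order.append(u)
                stack.append(u)
    below: dict[int, int] = {}
    for v in reversed(order):
        m = (1 << tindex[backbone.leaf_label(v)]) if backbone.is_leaf(v) else 0
        for u in backbone.neighbors(v):
            if u != parent[v]:
                m |= below[u]
        below[v] = m
    best_edge, best_cost = None, n + 1
    for v in order[1:]:
        e = (parent[v], v) if parent[v] < v else (v, parent[v])
        x = (below[v] ^ target).bit_count()
        cost = min(x, n - x)
        if cost < best_cost or (cost == best_cost and e < best_edge):
            best_edge, best_cost = e, cost
    return best_edge


def insertion_error_audit(reference: Topology, taxa_order: Sequence[str],
                          oracle: DistanceOracle, config: SNJConfig
                          ) -> list[int]:
    """Per-insertion edge displacement against a reference tree.

    The backbone starts from the usual sampled initial tree; each remaining
    taxon (in ``taxa_order``) is placed by the sparse recursion, the
    displacement between the chosen edge and the reference attachment edge
    is recorded, and the leaf is then inserted at its *reference* position
    so that errors do not accumulate.  Returns one displacement per
    insertion (n - k0 values).
    """
    taxa = list(taxa_order)
    ref_taxa = set(reference.leaf_labels.values())
    missing = [t for t in taxa if t not in ref_taxa]
    if missing:
        raise ValueError(f"taxa missing from the reference tree: {missing[:3]}")
    ss = np.random.SeedSequence(config.seed)
    s_backbone, _, s_place = ss.spawn(3)
    given = SNJConfig(mode=config.mode, k0=config.k0,
                      samples_per_subtree=config.samples_per_subtree,
                      orienting_per_subtree=config.orienting_per_subtree,
                      seed=config.seed, insertion_order="given")
    backbone, rest = initial_backbone(
        taxa, oracle, given, np.random.default_rng(s_backbone))
    place_rng = np.random.default_rng(s_place)
    n = len(taxa)
    displacements = []
    for taxon in rest:
        chosen = place_leaf(backbone, taxon, oracle, given, place_rng,
                            n_total=n)
        ref_edge = _reference_attachment_edge(backbone, taxon, reference)
        displacements.append(edge_displacement(backbone, chosen, ref_edge))
        backbone.insert_leaf(ref_edge, taxon)
    return displacements
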