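"""Pairwise evolutionary distances behind a memoizing, query-counting oracle.

The sparse-inference algorithm never materialises a dense distance matrix;
every distance it needs flows through a :class:`DistanceOracle`, which caches
computed entries and counts *distinct* unordered pairs ever evaluated.  That
counter is the operational definition of the method's sparsity: the fraction
of all n(n-1)/2 pairs actually touched.

Three backings are provided:

* :class:`SequenceDistanceOracle` — aligned DNA sequences, Jukes–Cantor or
  raw mismatch-proportion (Hamming) distances with pairwise deletion of
  gap/ambiguous sites;
* :class:`TreeDistanceOracle` — exact path-length sums on a weighted tree
  (constant-time per query via an Euler-tour lowest-common-ancestor table),
  the noiseless additive oracle used in recovery experiments;
* :class:`MatrixDistanceOracle` — a precomputed matrix.

The Jukes–Cantor maximum-likelihood branch-length estimator is
``d = -(3/4) ln(1 - (4/3) p)`` with ``p`` the mismatch proportion over
comparable sites; it saturates (is undefined) at ``p >= 3/4``, where a
configurable finite cap is returned instead.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SequenceMatrix",
    "DistanceOracle",
    "SequenceDistanceOracle",
    "TreeDistanceOracle",
    "MatrixDistanceOracle",
    "PerturbedTreeOracle",
    "hamming_mismatch",
    "jc_distance",
    "JC_SATURATION",
]

JC_SATURATION = 0.75

# DNA encoding: A,C,G,T -> 0..3; every other symbol (gaps, ambiguity codes,
# unknown characters) -> 4 and is excluded pairwise from distance counts.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _CODE[ord(_ch)] = _i
    _CODE[ord(_ch.lower())] = _i
_DECODE = np.frombuffer(b"ACGT-", dtype="S1")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes (non-ACGT symbols -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


class SequenceMatrix:
    """An aligned n x m DNA character matrix with unique taxon names."""

    def __init__(self, taxa: Sequence[str], codes: np.ndarray) -> None:
        taxa = list(taxa)
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names in alignment")
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2 or codes.shape[0] != len(taxa):
            raise ValueError("codes must be an (n_taxa, n_sites) matrix")
        self.taxa = taxa
        self.codes = codes
        self._idx = {t: i for i, t in enumerate(taxa)}

    @classmethod
    def from_sequences(cls, items: Iterable[tuple[str, str]]) -> "SequenceMatrix":
        taxa, rows = [], []
        m = None
        for name, seq in items:
            if m is None:
                m = len(seq)
            elif len(seq) != m:
                raise ValueError(
                    f"ragged alignment: sequence {name!r} has length "
                    f"{len(seq)}, expected {m}")
            taxa.append(name)
            rows.append(encode_sequence(seq))
        if not taxa:
            raise ValueError("empty alignment")
        return cls(taxa, np.vstack(rows))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self._idx[taxon]]

    def sequence(self, taxon: str) -> str:
        return decode_sequence(self.row(taxon))


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode_sequence(seq)
    return np.asarray(seq, dtype=np.uint8)


def hamming_mismatch(seq_i, seq_j) -> tuple[int, int]:
    """Count (mismatches, comparable sites) between two aligned sequences.

    A site is comparable when both characters are plain A/C/G/T; gap or
    ambiguous symbols remove the site from both counts (pairwise deletion).
    """
    a, b = _as_codes(seq_i), _as_codes(seq_j)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]} sites")
    valid = (a < 4) & (b < 4)
    comparable = int(np.count_nonzero(valid))
    mismatch = int(np.count_nonzero((a != b) & valid))
    return mismatch, comparable


def jc_distance(mismatch: int, sites: int, cap: float = 10.0) -> float:
    """Jukes–Cantor ML distance from a mismatch count.

    Returns ``-(3/4) ln(1 - (4/3) mismatch/sites)`` in expected
    substitutions per site, or ``cap`` when the estimator is saturated
    (mismatch proportion >= 3/4).
    """
    if sites < 1:
        raise ValueError("no comparable sites between the two sequences")
    if not 0 <= mismatch <= sites:
        raise ValueError("mismatch count outside [0, sites]")
    p = mismatch / sites
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return float(cap)
    return -0.75 * math.log(arg)


class DistanceOracle:
    """Symmetric pairwise-distance source with memoization and counting.

    ``distinct_query_count`` equals the number of unordered pairs ever
    computed; repeated queries hit the cache and do not increment it.
    Self-distances are 0 and are never counted.
    """

    def __init__(self, taxa: Sequence[str]) -> None:
        taxa = list(taxa)
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names")
        self.taxa = taxa
        self._idx = {t: i for i, t in enumerate(taxa)}
        self._n = len(taxa)
        self._cache: dict[int, float] = {}
        self.distinct_query_count = 0
        self.saturated_pairs = 0

    def _compute(self, i: int, j: int) -> float:  # pragma: no cover
        raise NotImplementedError

    def index(self, taxon: str) -> int:
        try:
            return self._idx[taxon]
        except KeyError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def query(self, taxon_i: str, taxon_j: str) -> float:
        i, j = self.index(taxon_i), self.index(taxon_j)
        if i == j:
            return 0.0
        if i > j:
            i, j = j, i
        key = i * self._n + j
        d = self._cache.get(key)
        if d is None:
            d = float(self._compute(i, j))
            self._cache[key] = d
            self.distinct_query_count += 1
        return d

    @property
    def total_pairs(self) -> int:
        return self._n * (self._n - 1) // 2

    @property
    def query_fraction(self) -> float:
        return self.distinct_query_count / self.total_pairs

    def matrix(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Dense matrix over ``subset`` (default: all taxa), via `query`."""
        names = list(subset) if subset is not None else self.taxa
        k = len(names)
        D = np.zeros((k, k), dtype=float)
        for a in range(k):
            for b in range(a + 1, k):
                D[a, b] = D[b, a] = self.query(names[a], names[b])
        return D


class SequenceDistanceOracle(DistanceOracle):
    """JC or Hamming distances computed on demand from aligned sequences."""

    def __init__(self, seqs: SequenceMatrix, model: str = "jc",
                 cap: float = 10.0) -> None:
        if model not in ("jc", "hamming"):
            raise ValueError(f"unknown distance model {model!r}")
        super().__init__(seqs.taxa)
        self._codes = seqs.codes
        self.model = model
        self.cap = float(cap)

    def _compute(self, i: int, j: int) -> float:
        mism, comp = hamming_mismatch(self._codes[i], self._codes[j])
        if self.model == "hamming":
            return mism / comp if comp else 0.0
        if comp >= 1 and mism / comp >= JC_SATURATION:
            self.saturated_pairs += 1
        return jc_distance(mism, comp, cap=self.cap)


class TreeDistanceOracle(DistanceOracle):
    """Exact path-length distances on a weighted tree (additive oracle).

    Accepts any object with ``topology`` and ``branch_lengths`` attributes
    (see :class:`sparsenj.simulate.WeightedTree`).  Queries are O(1) via an
    Euler-tour sparse table for lowest common ancestors.
    """

    def __init__(self, weighted_tree) -> None:
        top = weighted_tree.topology
        lengths = weighted_tree.branch_lengths
        super().__init__(top.leaves())
        nodes = top.nodes()
        root = min(v for v in nodes if not top.is_leaf(v))
        n_ids = max(nodes) + 1

        parent = np.full(n_ids, -1, dtype=np.int64)
        wdepth = np.zeros(n_ids, dtype=float)
        idepth = np.zeros(n_ids, dtype=np.int64)
        euler: list[int] = []
        first = np.full(n_ids, -1, dtype=np.int64)

        stack: list[tuple[int, int]] = [(root, -1)]
        # iterative Euler tour: re-push the parent after each child subtree
        order: list[tuple[int, int]] = [(root, -1)]
        while stack:
            v, par = stack.pop()
            for u in top.neighbors(v):
                if u != par:
                    parent[u] = v
                    e = (v, u) if v < u else (u, v)
                    wdepth[u] = wdepth[v] + lengths[e]
                    idepth[u] = idepth[v] + 1
                    stack.append((u, v))
                    order.append((u, v))
        # build the euler sequence from the parent structure
        children: dict[int, list[int]] = {}
        for u, par in order[1:]:
            children.setdefault(par, []).append(u)
        walk: list[tuple[int, bool]] = [(root, False)]
        while walk:
            v, done = walk.pop()
            euler.append(v)
            if not done:
                kids = children.get(v, [])
                for u in reversed(kids):
                    walk.append((v, True))
                    walk.append((u, False))
        euler_arr = np.asarray(euler, dtype=np.int64)
        for pos in range(len(euler_arr) - 1, -1, -1):
            first[euler_arr[pos]] = pos
        # something visited twice keeps its first position (reverse loop)

        depth_seq = idepth[euler_arr]
        m = len(euler_arr)
        levels = max(1, m.bit_length())
        sp = np.empty((levels, m), dtype=np.int64)
        sp[0] = np.arange(m)
        span = 1
        for k in range(1, levels):
            prev = sp[k - 1]
            upper = m - span
            left = prev[:upper]
            right = prev[span: span + upper]
            take_right = depth_seq[right] < depth_seq[left]
            sp[k, :upper] = np.where(take_right, right, left)
            sp[k, upper:] = prev[upper:]
            span *= 2

        self._first = first
        self._euler = euler_arr
        self._depth_seq = depth_seq
        self._sp = sp
        self._wdepth = wdepth
        self._leaf_node = np.asarray([top.leaf_node(t) for t in self.taxa],
                                     dtype=np.int64)

    def _lca(self, a: int, b: int) -> int:
        l, r = self._first[a], self._first[b]
        if l > r:
            l, r = r, l
        k = int(r - l + 1).bit_length() - 1
        i1 = self._sp[k, l]
        i2 = self._sp[k, r - (1 << k) + 1]
        pos = i1 if self._depth_seq[i1] <= self._depth_seq[i2] else i2
        return int(self._euler[pos])

    def _compute(self, i: int, j: int) -> float:
        a, b = int(self._leaf_node[i]), int(self._leaf_node[j])
        c = self._lca(a, b)
        return float(self._wdepth[a] + self._wdepth[b] - 2.0 * self._wdepth[c])


class PerturbedTreeOracle(TreeDistanceOracle):
    """Additive tree distances plus deterministic bounded noise per pair.

    Each unordered pair receives an independent Uniform(-magnitude,
    +magnitude) perturbation, derived reproducibly from ``seed`` and the
    pair's indices.  Used to probe the convergence radius: recovery is
    guaranteed whenever ``magnitude`` is below half the shortest branch.
    """

    def __init__(self, weighted_tree, magnitude: float, seed: int = 0) -> None:
        super().__init__(weighted_tree)
        self.magnitude = float(magnitude)
        self._seed = int(seed)

    def _compute(self, i: int, j: int) -> float:
        d = super()._compute(i, j)
        rng = np.random.default_rng(np.random.SeedSequence((self._seed, i, j)))
        return d + rng.uniform(-self.magnitude, self.magnitude)


class MatrixDistanceOracle(DistanceOracle):
    """Oracle backed by a precomputed symmetric matrix.

    Asymmetries up to ``tol`` are symmetrized by averaging; larger ones are
    rejected.
    """

    def __init__(self, matrix: np.ndarray, taxa: Sequence[str],
                 tol: float = 1e-9) -> None:
        super().__init__(taxa)
        D = np.asarray(matrix, dtype=float)
        if D.shape != (self._n, self._n):
            raise ValueError("matrix shape does not match taxa")
        asym = np.max(np.abs(D - D.T)) if self._n else 0.0
        if asym > tol:
            raise ValueError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {tol:.3g}")
        self._D = (D + D.T) / 2.0
        np.fill_diagonal(self._D, 0.0)

    def _compute(self, i: int, j: int) -> float:
        return float(self._D[i, j])
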