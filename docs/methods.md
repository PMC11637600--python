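# Methods

## Model and procedure

`sparsenj` infers unrooted bifurcating topologies from pairwise distances
without materialising the distance matrix.  All distances flow through a
memoizing oracle; the number of *distinct* unordered pairs ever computed is
the method's cost model, on the argument that for m-site alignments each
entry costs O(m) (or worse) while all tree operations are m-free.

A run has two phases:

1. **Backbone.** k₀ taxa are sampled uniformly and joined with canonical
   NJ (textbook O(k₀³) recursion, join criterion D_ij − u_i − u_j, matrix
   update (D_ik + D_jk − D_ij)/2).  Branch lengths are never stored:
   placement only needs topology, and lengths can be fitted afterwards by
   any standard optimiser if wanted.
2. **Insertion.** Remaining taxa are placed one at a time by centroid
   recursion.  The current subtree S of the backbone is split at its
   centroid into three parts; each part contributes orienting leaves; a
   4-taxon NJ quartet over (new taxon, representatives a\*, b\*, c\*)
   selects the part to descend into; recursion stops at a single edge,
   which is subdivided to attach the new leaf.  Since each part holds at
   most ⌈L/2⌉ of the subtree's L leaves, an insertion resolves
   O(log k) quartets.

Parts sometimes own edges but no leaves (interior regions delimited by
earlier centroids).  Their orienting leaves are drawn from the backbone
component *covering* the part — the component behind the corresponding
centroid direction — which preserves the correctness argument because any
leaf behind that direction induces the same quartet side.

**Guarantees.** If every oracle answer is within λ(T)/2 of the true path
length (λ(T) = shortest branch), the initial NJ tree, every quartet, and
hence every placement are correct, so the output equals the true topology.
The same holds for the enhanced variant's set-averaged quartets: averaging
distances of leaves drawn from one centroid component shifts all relevant
four-point sums by a common offset plus a term bounded below by the
component's entry branch, preserving strict inequalities under < λ(T)/2
noise.  Consistency in m follows: the Jukes–Cantor estimator converges in
probability per pair, a union bound puts the whole (sparse) set of queried
entries inside the radius, and recovery becomes an almost-sure event as
m → ∞.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `mode` | `enhanced` | `basic`: k₀ = 4, one uniform orienting leaf per part. `enhanced`: everything below. |
| `k0` | ⌈√(n log₂ n)⌉, clamped to [4, n] | dense NJ on k₀ taxa costs k₀(k₀−1)/2 ≈ (n log₂ n)/2 queries, the same order as the insertion phase, so neither phase dominates. |
| `samples_per_subtree` | ⌈log₂ n⌉ | candidate leaves drawn (without replacement) per part, truncated to the part's leaf count; log₂ matches the halving recursion — any fixed base only changes constants. |
| `orienting_per_subtree` | 3 (enhanced), 1 (basic) | candidates closest to the new taxon kept per part; quartet entries are means over the kept sets (3×3 cross pairs). |
| `cap` | 10.0 subst./site | value returned for saturated pairs (mismatch proportion ≥ 3/4, where the JC estimator is undefined); saturated pairs are counted and participate in closest-leaf ranking at the cap. |
| `seed` | 0 | master seed; three named substreams drive backbone choice, insertion order, per-insertion sampling, so components are reproducible in isolation. |
| branch-length scale | 1e-3 | mean of the exponential branch prior in the simulator ("scale", i.e. mean, convention). |

Deterministic tie rules, everywhere: centroid = argmin of the maximum
component leaf count, then smallest node id; NJ joins the lexicographically
first minimising pair; closest-orienting ties break by taxon name; the
simulator's canonical Newick orders children by smallest descendant label.

## Synthetic data

The generator reproduces the standard benchmark recipe: topologies by
uniform random pairwise merging of components (the final degree-2 node is
suppressed), i.i.d. Exponential(mean 1e-3) branch lengths, and exact
Jukes–Cantor site evolution (uniform root sequence; per-edge substitution
probability (3/4)(1 − e^{−4t/3}); no discretised stepping).  JC is
reversible, so the arbitrary internal-node rooting does not affect the
leaf distribution — asserted statistically in the tests.

What this emulates well: the m > n regime, additive expectation, noise
that shrinks as 1/√m, trees with many very short branches (Exp(1e-3)
places ~39% of branches below 5×10⁻⁴).  What it does not: rate
heterogeneity across sites, indels/gaps (the distance code handles them by
pairwise deletion, but the simulator never produces them), non-JC
substitution structure, and alignment error.  Passing tests therefore
speak to algorithmic correctness and JC-consistency, not to robustness on
real alignments.

## Numerical and design choices

* **Centroid bound.** Jordan's lemma is stated "at most k/2"; for odd leaf
  counts the attainable guarantee is ⌈L/2⌉, which is what the code
  asserts.  Leaves are counted within the subtree view only.
* **Representation.** Subtree views are edge subsets of the shared
  backbone (the centroid is removed, its edges are not).  Views generated
  by the recursion are stored compactly as (anchor node, removed
  centroids) and traversed by numba-compiled kernels — the traversal work
  is the O(n²) m-free overhead, and the compiled kernels keep it in the
  tens of seconds even at n ≈ 2·10⁴.  Hand-built views with explicit edge
  sets use a plain-Python backend with identical tie rules; the two are
  cross-checked in the tests.
* **Gap handling.** Sites with any non-ACGT symbol in either sequence are
  excluded from both mismatch and comparable counts (pairwise deletion),
  and the comparable count is the JC denominator.
* **Transfer distance.** Averaged over the reference's non-trivial edges
  only — trivial (leaf) edges have transfer index identically 0 and would
  merely dilute the mean.  Candidate inferred edges do include trivial
  ones.  The normalisation is by the smaller side of the reference
  bipartition (not the (p−1) convention used in bootstrap-support work).
* **Quartet distance.** Exact enumeration up to 30 leaves; above that,
  uniform quadruple sampling (default 500,000) with the binomial standard
  error reported.  Induced quartet topologies come from four-point sums of
  topological distances; with multifurcating inputs, tied sums mark the
  quadruple unresolved and it counts as differing.
* **Edge displacement.** The number of edges strictly between two edges;
  adjacent edges are at distance 0, matching the audit's "edges between"
  reading.
* **Degenerate inputs.** 3-leaf backbones place via a single quartet
  round; n = 4 reduces to plain NJ; matrices asymmetric beyond 1e-9 are
  rejected (below, symmetrized by averaging); multifurcating Newick is
  rejected by the strict container but accepted by the comparison metrics
  through a generic adapter.
* **k₀ reading.** A backbone of "n log n" *leaves* is impossible for
  k₀ ≤ n; the query budget the same passage implies (≈ n log n initial
  distance computations) pins k₀ at √(n log n), which is what the default
  implements.  `k0` stays a user override.
* **Insertion order** is a uniform shuffle of the non-backbone taxa (the
  audit driver supports a caller-fixed order instead).

## Problem sizes in tests and the acceptance script

The suites run at the sizes the science needs but no larger: recovery
properties on 200 random trees with n ∈ [5, 200]; NJ correctness at
n ≤ 12 (500 trees); metric-oracle agreement exhaustively at 5–6 leaves and
on 200 random 7–8-leaf pairs; accuracy at n = 1000, m = 20,000 over three
seeds; sparsity measured once at n = 23,331 on a constant-time additive
oracle; the consistency trend at n = 50 across m ∈ {500, 2000, 8000,
32,000} with 20 seeds.

## Known limitations

* The consistency guarantee is asymptotic in m.  At the simulator's
  default branch scale, trees of even 50 taxa usually contain branches
  whose expected substitution count at m = 32,000 is below one — no
  distance method resolves those; finite-m runs should be read through
  the transfer/quartet metrics rather than exact-recovery counts.
* Accuracy degrades slowly with n at fixed m (fewer quartets see each
  region); the audit shows errors are overwhelmingly local, so a
  post-hoc local rearrangement step is the natural complement but is out
  of scope here.
* The dense-NJ subroutine is the textbook O(k³) loop, fine for the k₀
  values the defaults produce, not a standalone large-n baseline.
* Only the Jukes–Cantor model is implemented for sequences; other
  substitution models would slot into the oracle unchanged.
* Quartet-distance computation is O(n · 2n) memory for the topological
  distance matrices and is sampled, not exact, beyond 30 leaves.
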