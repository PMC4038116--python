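# Methods

## Search procedure

Enumeration operates on one partition (the *enumeration side*; `auto`
picks the smaller). The other side is held as bitmaps: one
arbitrary-precision integer per enumeration-side vertex encodes its
neighborhood, so the inner-loop primitives — neighborhood intersection
and popcount — are single integer operations regardless of partition
size.

Each search node is ⟨L, R, P, Q⟩ with L the common neighborhood of the
seed R, P the ordered candidates and Q the former candidates. Expanding
candidate x:

1. L′ = L ∩ N(x), R′ = R ∪ {x}.
2. If some v ∈ Q has N(v) ⊇ L′ the branch is pruned: v would extend
   every biclique in the subtree, so none is maximal. (Checked before any
   other set is built.)
3. Otherwise S = {v ∈ P∖{x} : N(v) ⊇ L′} is absorbed into R′, and
   (L′, R′) is emitted — it is maximal by construction. P′ keeps the
   candidates with 0 < |N(v) ∩ L′| < |L′|; Q′ keeps former candidates
   with a non-empty intersection (the rest can never fire step 2 deeper
   down).
4. On return x moves from P to Q. Under iMBEA, members of S whose
   neighborhood within the parent L equals N(x) move to Q as well: any
   biclique containing them without x is dominated by one containing
   both.
5. Under iMBEA, P is sorted by non-decreasing |N(v) ∩ L| when a node is
   created (a full stable sort; since L is fixed within a node the order
   stays valid, so selection is always "first of P"). Under MBEA, P keeps
   input order.

Each maximal biclique is emitted exactly once (intermediate nodes of the
tree are in one-to-one correspondence with maximal bicliques), streamed
to a consumer so the full result set never needs to be held in memory.
The traversal uses an explicit frame stack rather than interpreter
recursion, so depth is bounded by memory alone; the test suite drives a
150-deep leftmost branch with the recursion limit pinned at 60.

Determinism: given the same input order and algorithm variant, emission
order, tree statistics, and all file outputs are identical between runs.
Node counts reported in statistics count the root plus every candidate
expansion; `leaves_pruned` counts step-2 prunes.

## Twin reduction

Vertices with identical neighborhoods are merged into their
first-in-order representative. Merging one side can create new twins on
the other, so passes alternate sides until a fixpoint — the paper-level
description leaves single- versus both-sided reduction open; both-sided
to fixpoint is this package's choice, and it is exact (verified against
the brute-force oracle on every suite graph). Degree-0 vertices form one
block per partition, are dropped with a logged warning, and never
reappear, since bicliques require two non-empty sides. Expansion
substitutes each representative by its block and re-canonicalizes to the
original partition order.

## Random graph generators

`er_bipartite(m, n, p, seed)` includes each of the m·n edges
independently with probability p.

`cv_bipartite(m, n, mu, cv, seed)` assigns each smaller-partition vertex
a target degree and then samples that many distinct neighbors uniformly
from the larger partition. The degree law is a gamma with shape 1/CV² and
scale μ·CV² (mean μ, standard deviation μ·CV), rounded to the nearest
integer and clipped to [1, m]; CV = 0 degenerates to the constant
round(μ). The gamma is a deliberate choice among distributions matching
the two prescribed moments: non-negative, two-parameter, and smooth
across the CV range of interest. Clipping at 1 rather than 0 keeps every
generated vertex in play (degree-0 vertices would be dropped by reduction
anyway). The rounding/clipping perturbs the realized moments only at the
third decimal for μ = 450; sample-level deviation is dominated by
ordinary sampling noise (standard error of the mean over n = 1000
vertices is μ·CV/√1000 ≈ 17 at CV = 1.2), which is why the moment-recovery
test pools degrees over five fixed seeds instead of judging a single
1000-vertex sample against a 5% band that noise alone would breach one
time in five.

Reproducibility contract: all randomness flows through
`numpy.random.default_rng(seed)`; identical parameters and seed give the
identical edge set.

## Gene-set machinery

Score matrices (genes × gene sets, missing cells allowed) are binarized
with an inclusive threshold — `at_most` for p-value-like scores,
`at_least` for correlation-like scores; missing cells never produce an
edge, and the operation is monotone in the threshold.

For maximal bicliques of one graph the two containment orders are dual
(P-side containment reverses G-side containment); `check_duality`
verifies this on any result set and a failure indicates a non-maximal
input. `build_dag` orders bicliques by strict containment of gene-set
sides and keeps the transitive reduction, computed by pairwise
containment tests plus removal of implied arcs — O(k²) set operations
with an O(k³) reduction step, appropriate for desk-scale result sets
(thousands of bicliques). Distinct maximal bicliques cannot share a
P-side (equal P forces equal G by maximality), so duplicates are rejected
rather than merged. Arcs point from larger P(b) toward smaller P(b):
roots pair many gene sets with few shared genes, and descending an arc
narrows the function side while widening the gene side.

## Problem sizes in the test suite

Oracle-equivalence runs 220 random graphs (Erdős–Rényi m ≤ 40, n ≤ 12,
p ∈ [0.05, 0.6]; degree-controlled m ≤ 60, n ≤ 12) — sizes where the
2ⁿ-subset brute-force oracle is itself fast and trustworthy. The pruning
comparison uses 20 degree-controlled graphs at m = 2000, n = 200, μ = 60,
CV ∈ {0.6, 0.8, 1.0, 1.2}, large enough for tens of thousands of maximal
bicliques per graph while keeping the whole suite under a minute for that
check. The generators' moment recovery is checked at m = 10000, n = 1000,
μ = 450.

## Degenerate inputs and edge cases

Empty graphs enumerate to an empty result; density is an error (not 0/0)
when a partition is empty. Bicliques with an empty side are never
emitted or representable. Duplicate input edges are deduplicated with a
warning. Isolated vertices cannot be expressed in an edge list, so the
dimacs writer's problem line declares the counts a reader of its output
will observe; the reader strictly rejects problem lines that disagree
with the observed labels.

## Limitations

Synthetic graphs have independent or degree-driven edges; real gene-set
association graphs carry block and correlation structure (co-annotation,
shared pathways) that neither generator emulates, so the oracle and
pruning results demonstrate algorithmic correctness and relative search
effort, not absolute performance on biological matrices. Edges are
unweighted and undirected; quasi-bicliques (near-complete blocks) are out
of scope, as are approximate or top-k enumeration.
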