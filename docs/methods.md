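# Methods

## Objects

All machinery operates on undirected multigraphs (parallel edges and
loops allowed), held as `networkx.MultiGraph` with opaque vertex ids.
An unrooted phylogenetic network on a taxon set X is a connected simple
graph with no degree-2 vertices whose degree-1 vertices are bijectively
labeled by X (|X| ≥ 1); labels live in a separate map so graph
rewriting never touches label bookkeeping.  A network is *proper* when
removing any cut edge or cut vertex leaves components that each contain
a labeled leaf.  *Blocks* are maximal biconnected subgraphs; *blobs*
are the connected components left after deleting every cut edge (a
single vertex is a trivial blob, and a "non-trivial blob" means one
with at least two vertices).  Cut-edge detection is
multiplicity-aware: a parallel pair is never a bridge.

## The rewriting system

Four restriction operations generate everything: delete a degree-1
vertex, suppress a degree-2 vertex (loops at the vertex disqualify it;
suppression may create a parallel edge or, when both edge ends meet the
same neighbor, a loop), delete one copy of a parallel edge, delete a
loop.  Leaf shrinking applies operations until none is applicable, with
one guard: at two remaining vertices only parallel-copy and loop
deletions are offered, so the vertex count never drops below two.  The
reduction is confluent — the leaf shrink graph LS(G) is unique up to
isomorphism whatever order is used — so the implementation simply picks
an applicable operation per step.  Two order policies are exposed,
`deterministic` (lexicographically smallest by operation rank and
target) and `random` (seeded), precisely so that confluence is a
*testable* property rather than an assumption; the suite shrinks
hundreds of random multigraphs under five seeds each and demands
pairwise-isomorphic results.

The classical statement of leaf shrinking assumes at least two
degree-1 vertices.  We relax this (`require_leaves=False`, used
internally by the edge-basedness test): the same confluent rewriting is
well defined on any connected graph with ≥ 2 vertices, and the
relaxation is what makes the correspondence "edge-based ⟺ GSP" hold on
leafless graphs such as bare cycles.  The strict precondition remains
the default on the public `leaf_shrink`.

## Edge-basedness and GSP recognition — two routes

`is_edge_based` runs the leaf shrink reduction and checks for K2.
`is_gsp` decomposes into blocks and decides series-parallelness of each
block by an exhaustive memoized search over suppress/parallel-delete
sequences (a single greedy order could in principle get stuck; the
search cannot).  Both routes are cross-checked against each other
inside `is_gsp` on every call, and a third, classical characterization
— no K4 topological minor, decided by a brute-force search for four
branch vertices joined by six internally-disjoint paths — is kept
strictly as an independent test oracle, never as the production
decision procedure.  `reduce_to_edge` performs the guided backtracking
that reduces a GSP graph to any chosen edge (the endpoints are
protected from deletion/suppression); it powers the blob-decomposition
route, where each non-trivial blob is re-leafed with a pendant stub per
incident cut edge and tested independently.

Asymptotics are explicitly out of scope: GSP graphs admit linear-time
recognition, but for the network sizes this package targets (tens of
vertices) the exhaustive-per-block search is simpler and exact.

## Leaf connecting and provenance tags

Leaf connecting first reduces multi-leaf attachment points (keep one
leaf, suppress the vertex if it drops to degree 2 — this can never
create a parallel edge), giving the reduced leaf set X^r.  Then leaf
pairs are deleted and their attachment points joined; a join that would
duplicate an existing edge is replaced by the two-vertex gadget (two
length-2 paths through fresh vertices a, b plus the edge {a,b}); an odd
last leaf is absorbed by deletion + suppression, with a one-vertex
gadget when the suppression would create a parallel edge.  Because the
pairing order can change the result, LCON(N) is computed over *all*
orders of pair selection and deduplicated by provenance-preserving
isomorphism (edge tags must match under the isomorphism; collapsing
tags could merge outputs that differ for the criteria below).  Every
edge carries a tag — `original`, `pair-join`, `gadget`, `last-leaf` —
and gadget vertices from pair joins are recorded separately from
last-leaf gadget vertices.  That annotation is exactly what the two
LCON-based criteria need: a Hamiltonian cycle through a `pair-join` or
`gadget` edge certifies tree-basedness, and a Hamiltonian member whose
pair join required the two-vertex gadget certifies it independently.
An exploration cap bounds the number of intermediate states; a capped
run returns the partial set flagged incomplete, and criteria treat an
incomplete set without a witness as indeterminate, never as false.

## Tree-basedness

The exact oracle enumerates spanning trees (`networkx`'s
SpanningTreeIterator) and accepts one whose leaf set equals X; every
bridge — in particular every pendant leaf edge — is automatically in
every spanning tree, which keeps the search small on sparse networks.
A cap bounds the number of trees examined and cap hits surface as
explicit indeterminates.

For proper edge-based networks the support tree is built
constructively: each cut-edge block contributes itself; each
series-parallel block with ≥ 3 vertices contributes a *valid spanning
tree* — one whose leaves all have degree 2 in the block — found by
spanning-tree enumeration with that constraint (existence is guaranteed
for SP blocks).  The assembled tree is re-verified before being
returned; verification failure would be a bug, not a data condition.

The binary-chordal certificate follows the constructive collapse: peel
leaves; inside a blob every degree-2 vertex of a chordal graph with
maximum degree 3 lies in a triangle, so suppress it and delete the
resulting parallel edge; degree-2 vertices on cut-edge chains between
blobs are plainly suppressed.  The triangle property is *checked* at
every iteration rather than assumed, so a precondition bug would
surface immediately.

Toughness t(G) = min |C| / c(G−C) over separating sets C is computed by
brute force over vertex subsets (Fractions, capped), returning +∞ for
complete graphs, where no separating set exists.  The tough-chordal
criterion requires a non-Hamiltonian LCUT and some chordal LCON member
with toughness ≥ 10.

Hamiltonian path/cycle and Hamilton-connectedness searches are exact
backtracking over the simple projection with degree-sorted expansion;
`None` means proven absent, and running out of budget raises instead of
guessing.  Conventions for degenerate sizes: the one-vertex graph and
K2 are Hamilton connected (so the "single vertex / single edge /
triangle" leaf-cut characterization composes); the empty graph — the
leaf cut graph of the two-taxon single-edge network — is *not* counted
as Hamilton connected, which keeps that characterization exact over
the enumeration.

## Synthetic data

The generators produce networks with constructive ground truth, and the
defaults are the regimes the verification suites run at:

* `gen_gsp_network(n_ops, seed)` composes K2s by series / parallel /
  generalized-series operations (default 6 compositions, giving cores
  of roughly 4–10 vertices), takes the underlying simple graph (which
  preserves the leaf shrink class), and attaches enough labeled leaves
  to lift every core vertex to degree ≥ 3.  Outputs are edge-based by
  construction and proper (every pendant block of a GSP core contains
  either a degree-≤2 vertex, which receives a leaf, or a core leaf,
  which receives two).
* `gen_tree_plus_edges(n_leaves, k_extra, seed)` grows a random binary
  tree by leaf insertion, then adds each extra edge between two fresh
  subdivision points of two distinct support-tree edges (distinctness
  avoids parallel edges; subdivision points end at degree 3).  The
  construction tree is returned and verified as a support tree.
* `gen_binary_chordal(n_blobs, blob_steps, seed)` plants blobs on a
  random binary backbone tree.  Each blob grows from a single edge by
  inverse triangle-collapse steps — double an edge whose endpoints both
  have degree ≤ 2, subdivide the new copy — which keeps chordality (the
  new vertex is simplicial) and maximum degree 3; leaves restore inner
  degree 3.  Under the degree constraint this growth reaches exactly
  {K2, triangle, diamond}, which are in fact the only non-trivial blobs
  a proper binary chordal network can have (a larger chordal block
  forces a vertex of degree > 3), so the generator covers the whole
  class shape-wise.
* `random_connected_multigraph` / `random_loopless_simple_graph` build
  the raw substrates (tree backbone plus random extra edges, parallel
  copies, loops; up to 10 vertices) for the confluence and equivalence
  suites.

What the synthetic regime does *not* emulate: networks reconstructed
from sequence data (no branch lengths, no reticulation-rate model, no
biological edge semantics).  Passing suites demonstrate the
combinatorial theorems and the correctness of the implementation on
the stated graph classes, not anything about empirical phylogenies.

`enumerate_networks(max_inner, max_leaves)` is exhaustive up to
isomorphism with exchangeable leaf labels: inner graphs come from the
networkx graph atlas (all connected simple graphs, ≤ 7 vertices; an
independent edge-subset enumerator cross-checks the counts in tests);
leaf distributions respect the degree-≥ 3 requirement of inner
vertices, are reduced to one representative per automorphism orbit of
the inner graph, and results are deduplicated per inner graph (the
inner graph is itself an isomorphism invariant, so cross-inner
comparisons are unnecessary).  The verification suites run the
exhaustive space at ≤ 6 inner vertices and ≤ 6 leaves (10,271
networks, about half a minute to enumerate and a couple of minutes to
sweep with the criteria and the oracle) — chosen as the largest space
that keeps the full suite comfortably interactive; the structural
statements it verifies are size-uniform.

## Numerical / combinatorial choices

* Isomorphism: cheap invariant fingerprint (vertex/edge counts, degree
  sequence, multiplicity multiset, loop count, optional vertex-kind
  profile) buckets candidates; VF2 (multigraph-aware) decides within a
  bucket.  No canonical forms — unnecessary at these sizes.
* Trace replay equality is vertex-set + edge-multiset equality; edge
  keys are bookkeeping.
* Deterministic tie-breaks everywhere (string-sorted vertices,
  operation ranks), so reductions, enumeration order and CLI output are
  reproducible; randomized paths take explicit seeds.
* Caps: every potentially exponential search (restricted-subgraph BFS,
  Hamiltonicity, spanning trees, toughness subsets, LCON orders) takes
  a cap and reports indeterminate rather than wrong answers on cap hit.
  The classifier records cap hits in the report (`caps_hit`) and the
  CLI maps them to exit code 2.

## Known limitations

* Exhaustive searches limit practical input sizes to a few dozen
  vertices; this is by design (certificates and exactness over speed).
* The H-connectedness of the empty leaf cut graph and Definition-level
  edge-basedness of leafless graphs are convention choices documented
  above; both are degenerate corners the theory leaves open.
* Perfect-graph generalizations of the binary-chordal result are noted
  in the literature but deliberately not implemented (only the
  chordality test is).
* Rooted networks, directed variants and weighted edges are out of
  scope.
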