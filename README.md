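# tbnet — classes of tree-based unrooted phylogenetic networks

`tbnet` classifies unrooted phylogenetic networks with respect to
*tree-basedness* and the classes that surround it.  It is aimed at
people working on phylogenetic network theory who want executable,
certificate-producing versions of the structural criteria, and at
practitioners who want a quick "is this network tree-based, and why"
answer for small networks.

## The problem

An unrooted phylogenetic network `N` on a taxon set `X` is a connected
simple graph with no degree-2 vertices whose degree-1 vertices are
bijectively labeled by `X`.  `N` is **tree-based** if it has a spanning
tree `T` (a *support tree*) whose leaf set is exactly `X`; suppressing
degree-2 vertices of `T` gives the *base tree*.  Deciding
tree-basedness is NP-complete, so sufficient criteria that are cheap to
verify matter.  `tbnet` implements three reductions of a network to
simpler graphs and the criteria they support:

* **Leaf cutting** `LCUT(N)`: delete all labeled leaves.  If `LCUT(N)`
  is Hamilton connected (`N` is *H-connected*), `N` is tree-based.
* **Leaf shrinking** `LS(N)`: exhaustively delete leaves, suppress
  degree-2 vertices, delete parallel copies and loops.  The result is
  unique up to isomorphism (the rewriting is confluent).  If `LS(N)`
  is a single edge `K2`, `N` is **edge-based** — and every edge-based
  proper network is tree-based, with an explicit support tree assembled
  from *valid spanning trees* of its blocks.  Edge-based networks are
  exactly the loopless **generalized series-parallel (GSP)** graphs,
  recognizable in linear time (here: block decomposition + exhaustive
  series-parallel reduction per block, fine for desk-scale networks).
* **Leaf connecting** `LCON(N)`: repeatedly delete a leaf pair and join
  their attachment points, inserting a two-vertex gadget when the join
  would create a parallel edge.  If some member of `LCON(N)` has a
  Hamiltonian cycle through a new (non-original, non-last-leaf) edge —
  in particular through a pair-join gadget — `N` is tree-based.

Further implemented facts: proper binary *chordal* networks are always
edge-based (with a constructive triangle-collapse certificate); a
network whose `LCUT` is non-Hamiltonian while some `LCON` member is a
10-tough chordal graph is tree-based; and, exhaustively verified over
all proper networks with ≤ 6 inner vertices and ≤ 6 leaves, a network
that is both edge-based and H-connected has `LCUT` equal to a single
vertex, a single edge, or a triangle.

## Worked example

```python
import tbnet

net = tbnet.fixture("FIX-A")      # triangle + pendant vertex, 4 taxa
rep = tbnet.classify(net)
print(rep.edge_based, rep.tree_based, rep.tree_based_method, rep.h_connected)
# True True edge-based False

st = rep.witnesses["support_tree"]
print(sorted(st.edges()))
# [('1', 's'), ('2', 's'), ('3', 'p'), ('4', 'q'), ('p', 'q'), ('p', 'w'), ('s', 'w')]

from tbnet.cli_io import write_tree
print(write_tree(st, "newick"))
# (3,4,(1,2));
```

The network shrinks to a single edge (`LS` passes through a triangle),
so it is edge-based and the support tree above is assembled from its
blocks: the triangle block contributes a two-edge path, every cut edge
contributes itself.  Its leaf cut graph keeps an unlabeled pendant
vertex, so it is not Hamilton connected — tree-basedness here comes
from edge-basedness, not from the Hamiltonicity route.

The same is available from the shell:

```
tbnet generate --kind gsp --seed 3 --out net.graphml
tbnet classify net.graphml          # JSON report, exit 0/2/1
tbnet reduce ls net.graphml         # leaf shrink graph + trace
tbnet support-tree net.graphml      # support tree + base-tree Newick
tbnet enumerate --max-inner 3 --max-leaves 4
```

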