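"""The leaf connecting procedure.

Leaf connecting turns a (non-tree) network into degree-1-free simple
graphs by repeatedly deleting a pair of leaves and joining their
attachment points.  When the join would create a parallel edge, a
two-vertex gadget (two length-2 paths through fresh vertices a, b plus
the edge {a, b}) keeps the graph simple; an odd final leaf has its own
one-vertex gadget rule.  The order in which pairs are chosen can change
the outcome, so the procedure is evaluated over *all* pair orders and
the results are collected up to (provenance-preserving) isomorphism:
that set is LCON(N).

Every edge of an output graph carries a provenance tag:

* ``original``  -- edge of the (pre-processed) input network
* ``pair-join`` -- plain join edge between two attachment points
* ``gadget``    -- edge of a two-vertex gadget from a pair join
* ``last-leaf`` -- edge introduced while removing the odd last leaf

The tags are what make the Hamiltonicity-based tree-basedness criteria
decidable from the output alone: a Hamiltonian cycle certifies
tree-basedness when it uses a ``pair-join`` or ``gadget`` edge, and the
pair-join gadget vertices witness the stronger criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import networkx.algorithms.isomorphism as nxiso

from ._iso import invariant_key
from .errors import PreconditionError
from .graphcore import PhyloNetwork, Vertex
from .reduce import SUPPRESS, RestrictionOp, apply_op

TAG = "tag"
ORIGINAL = "original"
PAIR_JOIN = "pair-join"
GADGET = "gadget"
LAST_LEAF = "last-leaf"


@dataclass
class AnnotatedGraph:
    """A leaf-connect output graph with edge provenance."""

    graph: nx.MultiGraph
    pair_gadget_vertices: set = field(default_factory=set)
    last_leaf_gadget_vertices: set = field(default_factory=set)
    xr_size: int = 0

    @property
    def new_vertices(self) -> set:
        return self.pair_gadget_vertices | self.last_leaf_gadget_vertices

    @property
    def edge_tags(self) -> dict[tuple, str]:
        return {tuple(sorted((u, v), key=str)): d[TAG]
                for u, v, d in self.graph.edges(data=True)}

    def to_graphml(self) -> str:
        """GraphML with an edge attribute ``provenance`` and a graph
        attribute ``xr_size``."""
        import io

        g = nx.MultiGraph()
        g.graph["xr_size"] = self.xr_size
        g.add_nodes_from(self.graph.nodes())
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, provenance=d[TAG])
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()

    def check_invariants(self, n_input_vertices: int) -> None:
        g = self.graph
        assert all(g.degree(v) >= 2 for v in g.nodes()), "degree-1 vertex in LCON output"
        assert not any(u == v for u, v in g.edges()), "loop in LCON output"
        assert all(g.number_of_edges(u, v) == 1 for u, v in g.edges()), \
            "parallel edge in LCON output"
        assert g.number_of_nodes() <= n_input_vertices, \
            "LCON output grew beyond the input network"
        for v in self.new_vertices:
            assert all(g.edges[e][TAG] in (GADGET, LAST_LEAF)
                       for e in _incident(g, v)), "gadget vertex with original edge"


def _incident(g: nx.MultiGraph, v):
    return [(a, b, k) for a, b, k in g.edges(v, keys=True)]


@dataclass
class LconResult:
    graphs: list[AnnotatedGraph]
    complete: bool = True


def preprocess(network: PhyloNetwork) -> PhyloNetwork:
    """Reduce multi-leaf attachment points: keep one leaf per inner
    vertex, suppressing any vertex that drops to degree 2; repeats
    until stable.  Defined (like the whole procedure) only for
    networks that are not trees."""
    if network.is_tree():
        raise PreconditionError("lcon-undefined-for-trees")
    if len(network.labels) < 2:
        raise PreconditionError("leaf connecting needs |X| >= 2")
    g = network.graph.copy()
    labels = dict(network.labels)
    changed = True
    while changed:
        changed = False
        label_of = {v: x for x, v in labels.items()}
        for v in sorted((n for n in g.nodes() if n not in label_of), key=str):
            attached = sorted((nb for nb in g.neighbors(v) if nb in label_of),
                              key=lambda w: label_of[w])
            if len(attached) >= 2:
                for leaf in attached[1:]:
                    del labels[label_of[leaf]]
                    g.remove_node(leaf)
                if g.degree(v) == 2:
                    before = g.number_of_edges()
                    apply_op(g, RestrictionOp(SUPPRESS, v))
                    # suppression here joins a leaf to an inner vertex and
                    # can never create a parallel edge
                    assert all(g.number_of_edges(a, b) == 1 for a, b in g.edges())
                changed = True
                break
    return PhyloNetwork(g, labels)


def lcon(network: PhyloNetwork, cap: int = 100000) -> LconResult:
    """Enumerate LCON(N) over all leaf-pairing orders.

    Outputs are deduplicated by provenance-aware isomorphism (edge tags
    must match under the isomorphism).  A cap bounds the number of
    explored intermediate states; if hit, the partial set is returned
    flagged incomplete.
    """
    net = preprocess(network)
    xr = sorted(net.labels)
    n_input = net.graph.number_of_nodes()
    g0 = net.graph.copy()
    for u, v, k in g0.edges(keys=True):
        g0.edges[u, v, k][TAG] = ORIGINAL

    out = _TaggedIsoSet()
    budget = [cap]
    complete = True

    def step(g: nx.MultiGraph, leaves: dict[str, Vertex],
             pair_gadgets: set, last_gadgets: set, fresh: int) -> None:
        nonlocal complete
        budget[0] -= 1
        if budget[0] < 0:
            complete = False
            return
        if len(leaves) == 0:
            ann = AnnotatedGraph(g, set(pair_gadgets), set(last_gadgets), len(xr))
            ann.check_invariants(n_input)
            out.add(ann)
            return
        if len(leaves) == 1:
            x, leaf = next(iter(leaves.items()))
            g2, last2, fresh2 = _remove_last_leaf(g, leaf, set(last_gadgets), fresh)
            step(g2, {}, pair_gadgets, last2, fresh2)
            return
        for x1, x2 in combinations(sorted(leaves), 2):
            g2, pg2, fresh2 = _join_pair(g, leaves[x1], leaves[x2],
                                         set(pair_gadgets), fresh)
            rest = {x: v for x, v in leaves.items() if x not in (x1, x2)}
            step(g2, rest, pg2, last_gadgets, fresh2)

    step(g0, dict(net.labels), set(), set(), 0)
    return LconResult(sorted(out, key=lambda a: invariant_key(a.graph)),
                      complete=complete)


def _join_pair(g, leaf1, leaf2, pair_gadgets, fresh):
    g = g.copy()
    u1 = next(iter(g.neighbors(leaf1)))
    u2 = next(iter(g.neighbors(leaf2)))
    assert u1 != u2, "pre-processing leaves at most one leaf per vertex"
    g.remove_node(leaf1)
    g.remove_node(leaf2)
    if g.has_edge(u1, u2):
        a, b, fresh = f"_a{fresh}", f"_b{fresh}", fresh + 1
        g.remove_edge(u1, u2)
        for e in ((u1, a), (a, u2), (u1, b), (b, u2), (a, b)):
            g.add_edge(*e, **{TAG: GADGET})
        pair_gadgets |= {a, b}
    else:
        g.add_edge(u1, u2, **{TAG: PAIR_JOIN})
    return g, pair_gadgets, fresh


def _remove_last_leaf(g, leaf, last_gadgets, fresh):
    g = g.copy()
    u = next(iter(g.neighbors(leaf)))
    g.remove_node(leaf)
    if g.degree(u) == 2:
        y, z = [w for _, w in g.edges(u)]
        if g.has_edge(y, z):
            # suppression would create a parallel edge: keep u on its
            # path, replace the existing {y,z} edge by a path through a
            # fresh vertex, and tie u to it
            a, fresh = f"_c{fresh}", fresh + 1
            g.remove_edge(y, z)
            for e in ((y, a), (a, z), (u, a)):
                g.add_edge(*e, **{TAG: LAST_LEAF})
            last_gadgets |= {a}
        else:
            g.remove_node(u)
            g.add_edge(y, z, **{TAG: LAST_LEAF})
    return g, last_gadgets, fresh


class _TaggedIsoSet:
    """Set of AnnotatedGraphs modulo tag-preserving isomorphism."""

    def __init__(self):
        self._buckets: dict[tuple, list[AnnotatedGraph]] = {}

    def __iter__(self):
        for b in self._buckets.values():
            yield from b

    def __len__(self):
        return sum(len(b) for b in self._buckets.values())

    def add(self, ann: AnnotatedGraph) -> bool:
        tags = tuple(sorted(d[TAG] for _, _, d in ann.graph.edges(data=True)))
        key = invariant_key(ann.graph) + (tags,)
        bucket = self._buckets.setdefault(key, [])
        em = nxiso.categorical_multiedge_match(TAG, None)
        for other in bucket:
            if nx.is_isomorphic(ann.graph, other.graph, edge_match=em):
                return False
        bucket.append(ann)
        return True
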