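"""Tree-basedness: the exact oracle, the constructive support-tree
builder for edge-based networks, the Hamiltonicity-based sufficient
criteria, chordality, toughness, and the combined classifier.

A network is *tree-based* when it has a spanning tree (a *support
tree*) whose leaves are exactly the labeled taxa X.  Deciding this is
NP-complete in general; the point of the surrounding machinery is a
collection of sufficient criteria that are much easier to check:

* edge-basedness (linear-time capable via GSP recognition) implies
  tree-basedness, with an explicit support tree assembled from valid
  spanning trees of the SP blocks;
* four Hamiltonicity criteria on the leaf cut graph LCUT and the leaf
  connect set LCON;
* binary + chordal implies edge-based, with a constructive
  triangle-collapse reduction as certificate;
* a toughness/chordality route (10-tough chordal graphs are
  Hamiltonian).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Optional, Union

import networkx as nx

from ._iso import is_k2
from .errors import CapExceeded, PreconditionError
from .graphcore import (PhyloNetwork, Vertex, decompose, is_proper,
                        simple_projection)
from .hamilton import (PathWitness, hamiltonian_cycle, hamiltonian_path,
                       is_hamilton_connected, is_hamiltonian)
from .lcon import GADGET, PAIR_JOIN, LconResult, lcon
from .reduce import (DELETE_LEAF, DELETE_PARALLEL, SUPPRESS, ReductionTrace,
                     RestrictionOp, apply_op, lcut)
from .spgsp import is_edge_based, is_sp


# ---------------------------------------------------------------------------
# Support trees

@dataclass
class SupportTree:
    """A spanning tree of a network whose leaves are exactly X."""

    tree: nx.Graph
    labels: dict[str, Vertex]

    def edges(self) -> list[tuple]:
        return sorted((tuple(sorted(e, key=str)) for e in self.tree.edges()),
                      key=lambda e: tuple(map(str, e)))

    def base_tree(self) -> tuple[nx.Graph, dict[str, Vertex]]:
        """Suppress degree-2 vertices of the support tree."""
        t = nx.Graph(self.tree)
        changed = True
        while changed:
            changed = False
            for v in list(t.nodes()):
                if t.degree(v) == 2 and v not in self.labels.values():
                    a, b = t.neighbors(v)
                    t.remove_node(v)
                    t.add_edge(a, b)
                    changed = True
        return t, dict(self.labels)

    def validate(self, network: PhyloNetwork) -> bool:
        t = self.tree
        if set(t.nodes()) != set(network.graph.nodes()):
            return False
        if not nx.is_tree(t):
            return False
        for u, v in t.edges():
            if not network.graph.has_edge(u, v):
                return False
        tree_leaves = {v for v in t.nodes() if t.degree(v) == 1}
        return tree_leaves == network.leaves


def is_tree_based_oracle(network: PhyloNetwork,
                         cap: int = 500000) -> tuple[bool, Optional[SupportTree]]:
    """Exact (exhaustive) tree-basedness decision.

    Enumerates spanning trees and checks for one whose leaf set equals
    X.  Every cut edge -- in particular every pendant leaf edge -- is
    automatically contained in every spanning tree, which prunes the
    space considerably.  ``cap`` bounds the number of trees examined.
    """
    g = simple_projection(network.graph)
    leaves = network.leaves
    examined = 0
    for tree in nx.SpanningTreeIterator(g):
        examined += 1
        if examined > cap:
            raise CapExceeded("is_tree_based_oracle", cap)
        tree_leaves = {v for v in tree.nodes() if tree.degree(v) == 1}
        if tree_leaves == leaves:
            return True, SupportTree(nx.Graph(tree), dict(network.labels))
    return False, None


def valid_spanning_tree(block: nx.MultiGraph, cap: int = 500000) -> nx.Graph:
    """A spanning tree of a simple biconnected SP block (or K2) whose
    leaves all have degree 2 in the block.

    Existence is guaranteed for SP blocks; the search is a plain
    spanning-tree enumeration with the leaf-degree constraint checked
    on each candidate.
    """
    s = simple_projection(block)
    if s.number_of_nodes() == 2 and s.number_of_edges() == 1:
        return nx.Graph(s)
    if not is_sp(block).verdict:
        raise PreconditionError("valid spanning trees exist only for SP blocks")
    deg2 = {v for v in s.nodes() if s.degree(v) == 2}
    examined = 0
    for tree in nx.SpanningTreeIterator(s):
        examined += 1
        if examined > cap:
            raise CapExceeded("valid_spanning_tree", cap)
        if all(v in deg2 for v in tree.nodes() if tree.degree(v) == 1):
            return nx.Graph(tree)
    raise AssertionError(  # pragma: no cover - contradicts SP structure
        "no valid spanning tree in an SP block")


def support_tree_edge_based(network: PhyloNetwork) -> SupportTree:
    """Constructive support tree for a proper edge-based network:
    take every cut-edge block verbatim and a valid spanning tree of
    every SP block with >= 3 vertices; their union is a support tree.
    The result is re-verified before being returned."""
    ok, _ = is_proper(network)
    if not ok or len(network.labels) < 2:
        raise PreconditionError("requires a proper network with |X| >= 2")
    if not is_edge_based(network, cross_check=False)[0]:
        raise PreconditionError("network is not edge-based")
    d = decompose(network.graph)
    t = nx.Graph()
    t.add_nodes_from(network.graph.nodes())
    for bvs in d.blocks:
        block = nx.MultiGraph(network.graph.subgraph(bvs).copy())
        if len(bvs) == 2:
            t.add_edge(*bvs)
        else:
            t.add_edges_from(valid_spanning_tree(block).edges())
    st = SupportTree(t, dict(network.labels))
    if not st.validate(network):  # pragma: no cover - would be a bug
        raise AssertionError("constructed support tree failed verification")
    return st


# ---------------------------------------------------------------------------
# Hamiltonicity criteria (sufficient conditions for tree-basedness)

def _require_proper(network: PhyloNetwork) -> None:
    ok, _ = is_proper(network)
    if not ok:
        raise PreconditionError("criterion requires a proper network")
    if len(network.labels) < 2:
        raise PreconditionError("criterion requires |X| >= 2")


def criterion_path(network: PhyloNetwork,
                   cap: int = 500000) -> tuple[bool, Optional[PathWitness]]:
    """Adjacent attachment points of two leaves joined by a path through
    all inner vertices."""
    _require_proper(network)
    if network.graph.number_of_nodes() == 2:
        return False, None
    cut = lcut(network)
    att = network.attachment_points
    tried = set()
    for x, y in combinations(sorted(att), 2):
        u, v = att[x], att[y]
        if u == v or (u, v) in tried:
            continue
        tried.add((u, v))
        tried.add((v, u))
        if not network.graph.has_edge(u, v):
            continue
        if cut.number_of_nodes() == 2:
            return True, PathWitness([u, v], "path")
        w = hamiltonian_path(cut, u, v, cap=cap)
        if w is not None:
            return True, w
    return False, None


def criterion_h_connected(network: PhyloNetwork, cap: int = 500000) -> bool:
    """Is the leaf cut graph Hamilton connected (H-connected network)?

    An empty leaf cut graph (the single-edge network) is not counted as
    Hamilton connected; one vertex or K2 are.
    """
    _require_proper(network)
    cut = lcut(network)
    if cut.number_of_nodes() == 0:
        return False
    return is_hamilton_connected(cut, cap=cap)


def _lcon_or_raise(network: PhyloNetwork, cap: int) -> LconResult:
    res = lcon(network, cap=cap)
    return res


def criterion_lcon_new_edge(network: PhyloNetwork,
                            cap: int = 100000) -> tuple[bool, Optional[dict]]:
    """Some leaf-connect graph has a Hamiltonian cycle through an edge
    that is neither original nor a last-leaf artifact."""
    _require_proper(network)
    if network.is_tree():
        raise PreconditionError("lcon-undefined-for-trees")
    res = _lcon_or_raise(network, cap)
    for ann in res.graphs:
        for (u, v), tag in sorted(ann.edge_tags.items(),
                                  key=lambda kv: tuple(map(str, kv[0]))):
            if tag not in (PAIR_JOIN, GADGET):
                continue
            h = ann.graph.copy()
            h.remove_edge(u, v)
            w = hamiltonian_path(h, u, v, cap=cap * 10)
            if w is not None:
                cycle = PathWitness(w.vertices, "cycle")
                return True, {"graph": ann, "edge": (u, v), "cycle": cycle}
    if not res.complete:
        raise CapExceeded("criterion_lcon_new_edge (incomplete LCON)", cap)
    return False, None


def criterion_lcon_gadget(network: PhyloNetwork,
                          cap: int = 100000) -> tuple[bool, Optional[dict]]:
    """Some Hamiltonian leaf-connect graph needed a two-vertex gadget
    while joining a leaf pair."""
    _require_proper(network)
    if network.is_tree():
        raise PreconditionError("lcon-undefined-for-trees")
    res = _lcon_or_raise(network, cap)
    for ann in res.graphs:
        if not ann.pair_gadget_vertices:
            continue
        w = hamiltonian_cycle(ann.graph, cap=cap * 10)
        if w is not None:
            return True, {"graph": ann, "cycle": w}
    if not res.complete:
        raise CapExceeded("criterion_lcon_gadget (incomplete LCON)", cap)
    return False, None


# ---------------------------------------------------------------------------
# Chordality, the binary-chordal reduction, toughness

def is_chordal(graph: Union[nx.MultiGraph, nx.Graph]) -> bool:
    """Perfect-elimination-ordering chordality test (simple graphs)."""
    if isinstance(graph, nx.MultiGraph):
        if any(u == v for u, v in graph.edges()) or \
                any(graph.number_of_edges(u, v) > 1 for u, v in graph.edges()):
            raise PreconditionError("chordality is defined for simple graphs")
        graph = simple_projection(graph)
    return nx.is_chordal(graph)


def chordal_binary_reduction(network: PhyloNetwork) -> ReductionTrace:
    """Constructive edge-basedness certificate for proper binary
    chordal networks.

    After peeling leaves, every degree-2 vertex inside a blob lies in a
    triangle (a consequence of chordality with maximum degree 3);
    suppressing it and deleting the resulting parallel edge shrinks the
    blob, and iterating collapses the whole network to a single edge.
    The triangle property is verified at run time on every iteration
    rather than assumed.
    """
    ok, _ = is_proper(network)
    if not ok or len(network.labels) < 2:
        raise PreconditionError("requires a proper network with |X| >= 2")
    if not network.is_binary():
        raise PreconditionError("not-binary")
    if not is_chordal(network.graph):
        raise PreconditionError("not-chordal")

    g = network.graph.copy()
    trace = ReductionTrace(initial=network.graph.copy())

    def do(op: RestrictionOp):
        apply_op(g, op)
        trace.steps.append(op)

    while not is_k2(g):
        if g.number_of_nodes() > 2:
            leaf = next((v for v in sorted(g.nodes(), key=str)
                         if g.degree(v) == 1), None)
            if leaf is not None:
                do(RestrictionOp(DELETE_LEAF, leaf))
                continue
            deg2 = [v for v in sorted(g.nodes(), key=str) if g.degree(v) == 2
                    and not g.number_of_edges(v, v)]
            tri = next((v for v in deg2
                        if _neighbors_adjacent(g, v)), None)
            if tri is not None:
                u, w = {b for _, b in g.edges(tri)}
                do(RestrictionOp(SUPPRESS, tri))
                do(RestrictionOp(DELETE_PARALLEL, tuple(sorted((u, w), key=str))))
                continue
            if deg2:
                # degree-2 vertex on a cut-edge chain between blobs
                do(RestrictionOp(SUPPRESS, deg2[0]))
                continue
        pair = next(((u, v) for u, v in g.edges()
                     if u != v and g.number_of_edges(u, v) >= 2), None)
        if pair is not None:
            do(RestrictionOp(DELETE_PARALLEL, tuple(sorted(pair, key=str))))
            continue
        raise AssertionError(  # pragma: no cover - contradicts Thm 6 preconds
            "binary chordal reduction stuck before reaching a single edge")
    trace.final = g.copy()
    return trace


def _neighbors_adjacent(g: nx.MultiGraph, v) -> bool:
    nbrs = {b for _, b in g.edges(v)}
    if len(nbrs) != 2:
        return False  # two parallel edges to one neighbor: no triangle
    a, b = nbrs
    return g.has_edge(a, b)


def toughness(graph: Union[nx.MultiGraph, nx.Graph],
              cap: int = 1 << 22) -> Union[Fraction, float]:
    """t(G) = min |C| / c(G - C) over separating vertex sets C;
    +infinity for complete graphs (no separating set exists)."""
    s = simple_projection(graph) if isinstance(graph, nx.MultiGraph) else graph
    n = s.number_of_nodes()
    if n == 0 or not nx.is_connected(s):
        raise PreconditionError("toughness requires a connected graph")
    best: Optional[Fraction] = None
    explored = 0
    nodes = sorted(s.nodes(), key=str)
    for size in range(1, n - 1):
        for C in combinations(nodes, size):
            explored += 1
            if explored > cap:
                raise CapExceeded("toughness", cap)
            h = s.copy()
            h.remove_nodes_from(C)
            ncomp = nx.number_connected_components(h)
            if ncomp >= 2:
                val = Fraction(size, ncomp)
                if best is None or val < best:
                    best = val
    return best if best is not None else math.inf


def criterion_tough_chordal(network: PhyloNetwork, cap: int = 100000,
                            tough_threshold: Fraction = Fraction(10)) -> bool:
    """LCUT not Hamiltonian, and some leaf-connect graph is a 10-tough
    chordal graph (such graphs are Hamiltonian, and the forced cycle
    must use a new edge, so tree-basedness follows via the new-edge
    criterion)."""
    _require_proper(network)
    cut = lcut(network)
    if cut.number_of_nodes() >= 3 and is_hamiltonian(cut):
        return False
    if network.is_tree():
        return False
    res = _lcon_or_raise(network, cap)
    for ann in res.graphs:
        try:
            if not is_chordal(ann.graph):
                continue
        except PreconditionError:
            continue
        if toughness(ann.graph) >= tough_threshold:
            return True
    if not res.complete:
        raise CapExceeded("criterion_tough_chordal (incomplete LCON)", cap)
    return False


# ---------------------------------------------------------------------------
# Combined classifier

@dataclass
class Caps:
    hamilton: int = 500000
    lcon: int = 100000
    spanning_trees: int = 500000
    toughness: int = 1 << 22


@dataclass
class ClassificationReport:
    proper: bool = False
    binary: bool = False
    chordal: bool = False
    simple_network: bool = False
    edge_based: bool = False
    gsp: bool = False
    h_connected: Optional[bool] = None
    tree_based: Optional[bool] = None
    tree_based_method: Optional[str] = None
    toughness_lcut: Optional[object] = None
    witnesses: dict = field(default_factory=dict)
    caps_hit: list = field(default_factory=list)
    caps: Optional[Caps] = None

    def to_json(self) -> dict:
        tough = self.toughness_lcut
        if isinstance(tough, Fraction):
            tough = {"num": tough.numerator, "den": tough.denominator}
        elif tough == math.inf:
            tough = "inf"
        wit = {}
        if "support_tree" in self.witnesses:
            wit["support_tree"] = [list(map(str, e))
                                   for e in self.witnesses["support_tree"].edges()]
        if "path" in self.witnesses:
            wit["path"] = list(map(str, self.witnesses["path"].vertices))
        return {
            "schema": 1,
            "proper": self.proper, "binary": self.binary,
            "chordal": self.chordal, "simple_network": self.simple_network,
            "edge_based": self.edge_based, "gsp": self.gsp,
            "h_connected": self.h_connected,
            "tree_based": self.tree_based,
            "tree_based_method": self.tree_based_method,
            "toughness_lcut": tough,
            "witnesses": wit,
            "caps_hit": list(self.caps_hit),
            "caps": vars(self.caps) if self.caps else None,
        }


def classify(network: PhyloNetwork, caps: Optional[Caps] = None) -> ClassificationReport:
    """Run the full battery of class tests, recording witnesses and any
    brute-force caps that were hit (indeterminate results are recorded,
    never silently coerced to False)."""
    from .graphcore import is_simple_network

    caps = caps or Caps()
    rep = ClassificationReport(caps=caps)
    g = network.graph
    rep.proper = is_proper(network)[0]
    rep.binary = network.is_binary()
    rep.chordal = is_chordal(g)
    rep.simple_network = is_simple_network(network)
    rep.edge_based, cert = is_edge_based(network, cross_check=False)
    rep.gsp = rep.edge_based  # network graphs are loopless: the classes coincide
    rep.witnesses["ls_trace"] = cert.trace

    usable = rep.proper and len(network.labels) >= 2
    if usable:
        try:
            rep.h_connected = criterion_h_connected(network, cap=caps.hamilton)
        except CapExceeded as e:
            rep.caps_hit.append(str(e))

    if rep.binary and rep.chordal and rep.proper and len(network.labels) >= 2:
        if not rep.edge_based:  # pragma: no cover - internal consistency
            raise AssertionError("binary chordal proper network not edge-based")

    # tree-basedness: cheapest certificate first
    if usable and rep.edge_based:
        st = support_tree_edge_based(network)
        rep.tree_based, rep.tree_based_method = True, "edge-based"
        rep.witnesses["support_tree"] = st
    elif g.number_of_nodes() == 2:
        rep.tree_based, rep.tree_based_method = True, "trivial"
    elif usable:
        found = False
        for name, fn in (
            ("attachment-path", lambda: criterion_path(network, cap=caps.hamilton)[0]),
            ("h-connected", lambda: rep.h_connected is True),
            ("lcon-new-edge", lambda: not network.is_tree()
             and criterion_lcon_new_edge(network, cap=caps.lcon)[0]),
            ("lcon-gadget", lambda: not network.is_tree()
             and criterion_lcon_gadget(network, cap=caps.lcon)[0]),
        ):
            try:
                if fn():
                    rep.tree_based, rep.tree_based_method = True, name
                    found = True
                    break
            except CapExceeded as e:
                rep.caps_hit.append(str(e))
        if not found:
            try:
                verdict, st = is_tree_based_oracle(network, cap=caps.spanning_trees)
                rep.tree_based, rep.tree_based_method = verdict, "oracle"
                if st is not None:
                    rep.witnesses["support_tree"] = st
            except CapExceeded as e:
                rep.caps_hit.append(str(e))
    else:
        try:
            verdict, st = is_tree_based_oracle(network, cap=caps.spanning_trees)
            rep.tree_based, rep.tree_based_method = verdict, "oracle"
            if st is not None:
                rep.witnesses["support_tree"] = st
        except CapExceeded as e:
            rep.caps_hit.append(str(e))

    try:
        cut = lcut(network) if len(network.labels) >= 2 else None
        if cut is not None and 0 < cut.number_of_nodes() <= 10:
            rep.toughness_lcut = toughness(cut, cap=caps.toughness)
    except (CapExceeded, PreconditionError):
        pass
    return rep
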