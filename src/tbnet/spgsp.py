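"""Series-parallel / generalized series-parallel recognition and the
edge-basedness machinery.

A connected loopless graph is *SP* if it can be reduced to the single
edge K2 by suppressing degree-2 vertices and deleting parallel copies
(operations 2-3); it is *GSP* if leaf deletion (operation 1) is allowed
as well.  A connected graph is *edge-based* when its leaf shrink graph
(operations 1-4) is K2.  The three notions interlock:

* GSP  <=>  every block is SP                      (block route)
* GSP  <=>  loopless and reducible by ops 1-4      (reduction route)
* GSP  <=>  loopless and edge-based

Both decision routes are implemented and must agree; the K4
topological-minor brute force is classical background used purely as an
independent test oracle (GSP graphs are exactly the connected partial
2-trees).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Union

import networkx as nx

from ._iso import is_k2, multiplicities
from .errors import CapExceeded, NotConnectedError, PreconditionError
from .graphcore import (PhyloNetwork, blob_subgraph, decompose, is_proper,
                        simple_projection)
from .reduce import (DELETE_LEAF, DELETE_PARALLEL, SUPPRESS, ReductionTrace,
                     RestrictionOp, apply_op, leaf_shrink)


@dataclass
class GspCertificate:
    verdict: bool
    route: str  # "reduction" | "block-sp" | "composition"
    trace: object = None  # ReductionTrace or list of blocks
    terminals: Optional[tuple] = None

    def to_json(self) -> dict:
        trace = self.trace
        if isinstance(trace, ReductionTrace):
            trace = trace.to_json()
        elif trace is not None:
            trace = [list(map(str, b)) for b in trace]
        return {"verdict": self.verdict, "route": self.route, "trace": trace,
                "terminals": list(map(str, self.terminals)) if self.terminals else None}


def _check_loopless_connected(g: nx.MultiGraph, what: str) -> None:
    if any(u == v for u, v in g.edges()):
        raise PreconditionError(f"{what} is defined for loopless graphs")
    if g.number_of_nodes() == 0 or not nx.is_connected(simple_projection(g)):
        raise NotConnectedError(f"{what} requires a connected graph")


def _state_key(g: nx.MultiGraph):
    return (frozenset(g.nodes()),
            frozenset(multiplicities(g).items()))


def _search_reduction(graph: nx.MultiGraph, ops_fn, done_fn,
                      cap: int = 50000) -> Optional[list[RestrictionOp]]:
    """DFS for an op sequence turning ``graph`` into a state accepted by
    ``done_fn``; exact-state memoization of failed states."""
    failed: set = set()
    budget = [cap]

    def dfs(g: nx.MultiGraph) -> Optional[list[RestrictionOp]]:
        if done_fn(g):
            return []
        key = _state_key(g)
        if key in failed:
            return None
        budget[0] -= 1
        if budget[0] < 0:
            raise CapExceeded("reduction search", cap)
        for op in ops_fn(g):
            nxt = g.copy()
            apply_op(nxt, op)
            rest = dfs(nxt)
            if rest is not None:
                return [op] + rest
        failed.add(key)
        return None

    return dfs(graph.copy())


def _sp_ops(g: nx.MultiGraph) -> list[RestrictionOp]:
    """Operations 2-3 with the two-vertex guard."""
    ops = []
    n = g.number_of_nodes()
    if n > 2:
        for v in g.nodes():
            if g.degree(v) == 2 and not g.number_of_edges(v, v):
                ops.append(RestrictionOp(SUPPRESS, v))
    seen = set()
    for u, v in g.edges():
        pair = frozenset((u, v))
        if u != v and pair not in seen and g.number_of_edges(u, v) >= 2:
            ops.append(RestrictionOp(DELETE_PARALLEL, tuple(sorted((u, v), key=str))))
        seen.add(pair)
    return sorted(ops, key=RestrictionOp.sort_key)


def is_sp(graph: nx.MultiGraph, cap: int = 50000) -> GspCertificate:
    """Is the graph series-parallel (reducible to K2 by ops 2-3)?

    Exhaustive (memoized) search, so a single stuck greedy order can
    never produce a false negative.
    """
    _check_loopless_connected(graph, "SP recognition")
    if graph.number_of_nodes() < 2:
        return GspCertificate(False, "reduction")
    steps = _search_reduction(graph, _sp_ops, is_k2, cap=cap)
    if steps is None:
        return GspCertificate(False, "reduction")
    trace = ReductionTrace(initial=graph.copy(), steps=steps)
    trace.final = trace.replay()
    return GspCertificate(True, "reduction", trace=trace)


def _block_subgraphs(g: nx.MultiGraph) -> list[nx.MultiGraph]:
    d = decompose(g)
    return [nx.MultiGraph(g.subgraph(b).copy()) for b in d.blocks]


def _blocks_all_sp(g: nx.MultiGraph, cap: int) -> tuple[bool, list]:
    blocks = _block_subgraphs(g)
    for b in blocks:
        if b.number_of_nodes() == 1:
            continue  # isolated vertex (only for K1 input)
        if not is_sp(b, cap=cap).verdict:
            return False, blocks
    return True, blocks


def is_gsp(graph: nx.MultiGraph, cap: int = 50000) -> GspCertificate:
    """GSP recognition via the block route, cross-checked against the
    ops-1-4 reduction route; the two must agree (internal error
    otherwise)."""
    _check_loopless_connected(graph, "GSP recognition")
    if graph.number_of_nodes() < 2:
        return GspCertificate(False, "block-sp")
    verdict, blocks = _blocks_all_sp(graph, cap)
    ls, trace = leaf_shrink(graph, require_leaves=False)
    reduction_verdict = is_k2(ls)
    if verdict != reduction_verdict:  # pragma: no cover - internal consistency
        raise AssertionError("block-SP route and reduction route disagree")
    if verdict:
        return GspCertificate(True, "block-sp", trace=trace)
    return GspCertificate(False, "block-sp",
                          trace=[tuple(sorted(b, key=str)) for b in
                                 (set(b.nodes()) for b in blocks)])


def is_edge_based(graph_or_network: Union[nx.MultiGraph, PhyloNetwork],
                  cross_check: bool = True) -> tuple[bool, GspCertificate]:
    """Edge-basedness: the leaf shrink graph is a single edge.

    Phylogenetic networks are accepted directly; raw graphs of any
    shape are reduced with the same confluent rewriting (the >= 2
    leaves clause of the classical definition is relaxed so that the
    GSP correspondence holds on leafless graphs such as cycles).

    For loopless inputs the verdict is cross-checked against the
    block-SP route; disagreement is an internal error.
    """
    g = graph_or_network.graph if isinstance(graph_or_network, PhyloNetwork) \
        else graph_or_network
    if g.number_of_nodes() < 2:
        raise PreconditionError("edge-basedness needs |V| >= 2")
    if not nx.is_connected(simple_projection(g)):
        raise NotConnectedError("edge-basedness requires a connected graph")
    ls, trace = leaf_shrink(g, require_leaves=False)
    verdict = is_k2(ls)
    if cross_check and not any(u == v for u, v in g.edges()):
        block_verdict, _ = _blocks_all_sp(g, cap=50000)
        if block_verdict != verdict:  # pragma: no cover
            raise AssertionError("edge-based (LS) and GSP (block) routes disagree")
    return verdict, GspCertificate(verdict, "reduction", trace=trace)


def has_k4_topological_minor(graph: nx.MultiGraph, cap: int = 2_000_000) -> bool:
    """Brute-force test for a K4 topological minor: four branch
    vertices joined by six internally-disjoint paths.

    Used strictly as an independent oracle in tests (connected loopless
    graph is GSP iff it has no K4 topological minor); never the
    production decision procedure.
    """
    s = simple_projection(graph)
    if s.number_of_nodes() < 4:
        return False
    budget = [cap]

    def connect(pairs: list[tuple], banned: set) -> bool:
        if not pairs:
            return True
        a, b = pairs[0]
        # DFS over simple a-b paths with internal vertices outside `banned`
        stack = [(a, [a])]
        while stack:
            cur, path = stack.pop()
            budget[0] -= 1
            if budget[0] < 0:
                raise CapExceeded("has_k4_topological_minor", cap)
            for nb in s.neighbors(cur):
                if nb == b:
                    if connect(pairs[1:], banned | set(path[1:])):
                        return True
                elif nb not in banned and nb not in path:
                    stack.append((nb, path + [nb]))
        return False

    for branch in itertools.combinations(sorted(s.nodes(), key=str), 4):
        bset = set(branch)
        pairs = list(itertools.combinations(branch, 2))
        # `banned` starts at the branch set and grows with internal
        # vertices already claimed by earlier paths
        if connect(pairs, set(bset)):
            return True
    return False


def edge_based_by_blobs(network: PhyloNetwork) -> bool:
    """Blob decomposition route: a proper network is edge-based iff
    every non-trivial blob (with its incident cut edges re-attached as
    pendant leaves) is edge-based.  Must agree with the whole-network
    test; disagreement is an internal error."""
    ok, _ = is_proper(network)
    if not ok:
        raise PreconditionError("blob decomposition requires a proper network")
    if len(network.labels) < 2:
        raise PreconditionError("blob decomposition requires |X| >= 2")
    d = decompose(network.graph)
    cut_pairs = [e for e, _ in d.cut_edges]
    verdict = True
    for blob, trivial in d.blobs:
        if trivial:
            continue
        piece = blob_subgraph(network.graph, blob)
        bset = set(blob)
        for (u, v) in cut_pairs:
            if u in bset and v not in bset:
                piece.add_edge(u, f"_stub_{v}")
            elif v in bset and u not in bset:
                piece.add_edge(v, f"_stub_{u}")
        if not is_edge_based(piece, cross_check=False)[0]:
            verdict = False
            break
    whole, _ = is_edge_based(network.graph, cross_check=False)
    if verdict != whole:  # pragma: no cover - internal consistency
        raise AssertionError("blob route disagrees with whole-network route")
    return verdict


def reduce_to_edge(graph: nx.MultiGraph, edge: tuple,
                   cap: int = 200000) -> ReductionTrace:
    """Reduce a GSP graph to one chosen edge by operations 1-3.

    Any edge of a GSP graph can serve as the terminal pair, so this
    guided backtracking search is guaranteed to succeed on GSP input;
    the cap is only a safety valve.
    """
    u, v = edge
    if not graph.has_edge(u, v):
        raise PreconditionError(f"edge {{{u},{v}}} not in graph")
    if not is_gsp(graph).verdict:
        raise PreconditionError("reduce_to_edge requires a GSP graph")
    protected = {u, v}

    def ops_fn(g: nx.MultiGraph) -> list[RestrictionOp]:
        ops = []
        if g.number_of_nodes() > 2:
            for w in g.nodes():
                if w in protected:
                    continue
                if g.degree(w) == 1:
                    ops.append(RestrictionOp(DELETE_LEAF, w))
                elif g.degree(w) == 2 and not g.number_of_edges(w, w):
                    ops.append(RestrictionOp(SUPPRESS, w))
        seen = set()
        for a, b in g.edges():
            pair = frozenset((a, b))
            if a != b and pair not in seen and g.number_of_edges(a, b) >= 2:
                ops.append(RestrictionOp(DELETE_PARALLEL, tuple(sorted((a, b), key=str))))
            seen.add(pair)
        return sorted(ops, key=RestrictionOp.sort_key)

    def done(g: nx.MultiGraph) -> bool:
        return (set(g.nodes()) == protected and g.number_of_edges() == 1
                and g.has_edge(u, v))

    steps = _search_reduction(graph, ops_fn, done, cap=cap)
    if steps is None:  # pragma: no cover - cannot happen for GSP inputs
        raise AssertionError("reduction to edge failed on a GSP graph")
    trace = ReductionTrace(initial=graph.copy(), steps=steps)
    trace.final = trace.replay()
    return trace


# ---------------------------------------------------------------------------
# Two-terminal compositions (used by generators and property tests)

def _disjointify(g1: nx.MultiGraph, t1: tuple, g2: nx.MultiGraph, t2: tuple):
    """Relabel g2 apart from g1; returns (g2', t2')."""
    mapping = {}
    taken = set(g1.nodes())
    for n in g2.nodes():
        new = n
        i = 0
        while new in taken:
            new = f"{n}~{i}"
            i += 1
        mapping[n] = new
        taken.add(new)
    return nx.relabel_nodes(g2, mapping, copy=True), (mapping[t2[0]], mapping[t2[1]])


def _merge(g1, t1, g2, t2, identify: list[tuple], new_terminals):
    g2, t2 = _disjointify(g1, t1, g2, t2)
    ident = {old: new for old, new in identify_pairs(identify, t1, t2)}
    g2 = nx.relabel_nodes(g2, ident, copy=True)
    out = g1.copy()
    out.add_nodes_from(g2.nodes())
    out.add_edges_from(g2.edges())
    a, b = new_terminals(t1, tuple(ident.get(x, x) for x in t2))
    return out, (a, b)


def identify_pairs(identify, t1, t2):
    for i, j in identify:
        yield t2[j], t1[i]


def series_compose(g1, t1, g2, t2):
    """Identify v1 with u2; terminals (u1, v2)."""
    return _merge(g1, t1, g2, t2, [(1, 0)], lambda a, b: (a[0], b[1]))


def parallel_compose(g1, t1, g2, t2):
    """Identify u1~u2 and v1~v2; terminals (u1, v1)."""
    return _merge(g1, t1, g2, t2, [(0, 0), (1, 1)], lambda a, b: (a[0], a[1]))


def generalized_series_compose(g1, t1, g2, t2):
    """Identify v1 with u2; terminals (u2, v2) -- g1 dangles off u2."""
    return _merge(g1, t1, g2, t2, [(1, 0)], lambda a, b: (a[1], b[1]))


def k2(u="u", v="v") -> tuple[nx.MultiGraph, tuple]:
    g = nx.MultiGraph()
    g.add_edge(u, v)
    return g, (u, v)
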