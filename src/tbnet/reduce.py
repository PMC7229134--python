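"""Restriction-operation rewriting: leaf cutting and leaf shrinking.

Four *restriction operations* generate the rewriting system:

1. ``delete-leaf``          -- delete a degree-1 vertex and its edge
2. ``suppress-degree2``     -- replace a degree-2 vertex by an edge
                               between its two neighbors
3. ``delete-parallel-copy`` -- delete one copy of a parallel edge
4. ``delete-loop``          -- delete a loop

A graph reachable by these operations is a *restricted topological
subgraph*.  Leaf shrinking applies operations until none is applicable,
subject to one guard: once only two vertices remain, only parallel-copy
and loop deletions are offered, so the vertex count never drops below
two.  The resulting leaf shrink graph LS(G) is unique up to isomorphism
regardless of the order in which applicable operations are picked
(confluence), which is why both a deterministic and a seeded random
policy are exposed: agreement between them is a testable property, not
an assumption.
"""

from __future__ import annotations

import json
import random
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from ._iso import IsoSet, graphs_equal, isomorphic
from .errors import CapExceeded, PreconditionError
from .graphcore import PhyloNetwork

DELETE_LEAF = "delete-leaf"
SUPPRESS = "suppress-degree2"
DELETE_PARALLEL = "delete-parallel-copy"
DELETE_LOOP = "delete-loop"

_RANK = {DELETE_LEAF: 0, SUPPRESS: 1, DELETE_PARALLEL: 2, DELETE_LOOP: 3}


@dataclass(frozen=True)
class RestrictionOp:
    """One rewriting step; ``target`` is a vertex id or an edge pair."""

    kind: str
    target: object

    def sort_key(self):
        t = self.target
        tkey = tuple(map(str, t)) if isinstance(t, tuple) else (str(t),)
        return (_RANK[self.kind], tkey)

    def to_json(self) -> dict:
        return {"kind": self.kind,
                "target": list(self.target) if isinstance(self.target, tuple)
                else self.target}

    @staticmethod
    def from_json(d: dict) -> "RestrictionOp":
        t = d["target"]
        return RestrictionOp(d["kind"], tuple(t) if isinstance(t, list) else t)


@dataclass
class ReductionTrace:
    """Certificate: replaying ``steps`` from ``initial`` gives ``final``.

    Graph equality here is vertex-set plus edge-multiset equality (edge
    keys are bookkeeping, not structure).
    """

    initial: nx.MultiGraph
    steps: list[RestrictionOp] = field(default_factory=list)
    final: Optional[nx.MultiGraph] = None

    def replay(self) -> nx.MultiGraph:
        g = self.initial.copy()
        for op in self.steps:
            apply_op(g, op)
        return g

    def verify(self) -> bool:
        return self.final is not None and graphs_equal(self.replay(), self.final)

    def to_json(self) -> str:
        return json.dumps({
            "initial": _graph_json(self.initial),
            "steps": [op.to_json() for op in self.steps],
            "final": _graph_json(self.final) if self.final is not None else None,
        })


def _graph_json(g: nx.MultiGraph) -> dict:
    return {"vertices": sorted(map(str, g.nodes())),
            "edges": sorted([str(u), str(v)] for u, v in g.edges())}


def applicable_ops(g: nx.MultiGraph) -> list[RestrictionOp]:
    """All currently legal restriction operations, honoring the
    two-vertex guard (only parallel-copy / loop deletions when |V| = 2).
    """
    ops: list[RestrictionOp] = []
    n = g.number_of_nodes()
    loops_at = {v for v in g.nodes() if g.number_of_edges(v, v) > 0}
    if n > 2:
        for v in g.nodes():
            if g.degree(v) == 1:
                ops.append(RestrictionOp(DELETE_LEAF, v))
            elif g.degree(v) == 2 and v not in loops_at:
                ops.append(RestrictionOp(SUPPRESS, v))
    seen_pairs = set()
    for u, v in g.edges():
        pair = frozenset((u, v))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        if u == v:
            ops.append(RestrictionOp(DELETE_LOOP, u))
        elif g.number_of_edges(u, v) >= 2:
            ops.append(RestrictionOp(DELETE_PARALLEL, tuple(sorted((u, v), key=str))))
    return sorted(ops, key=RestrictionOp.sort_key)


def apply_op(g: nx.MultiGraph, op: RestrictionOp) -> None:
    """Apply one restriction operation in place."""
    if op.kind == DELETE_LEAF:
        if g.degree(op.target) != 1:
            raise PreconditionError(f"{op.target} is not a leaf")
        g.remove_node(op.target)
    elif op.kind == SUPPRESS:
        v = op.target
        if g.degree(v) != 2 or g.number_of_edges(v, v):
            raise PreconditionError(f"{v} is not a suppressible degree-2 vertex")
        nbrs = [w for _, w in g.edges(v)]
        u, w = nbrs
        g.remove_node(v)
        g.add_edge(u, w)  # may create a parallel edge or (if u == w) a loop
    elif op.kind == DELETE_PARALLEL:
        u, v = op.target
        if g.number_of_edges(u, v) < 2:
            raise PreconditionError(f"{{{u},{v}}} is not a parallel edge")
        g.remove_edge(u, v)
    elif op.kind == DELETE_LOOP:
        v = op.target
        if not g.number_of_edges(v, v):
            raise PreconditionError(f"no loop at {v}")
        g.remove_edge(v, v)
    else:  # pragma: no cover
        raise ValueError(f"unknown op kind {op.kind}")


def leaf_shrink(graph: nx.MultiGraph, policy: str = "deterministic",
                seed: Optional[int] = None,
                require_leaves: bool = True) -> tuple[nx.MultiGraph, ReductionTrace]:
    """Fully reduce ``graph`` and return (LS(graph), trace).

    The classical statement of the procedure assumes at least two
    degree-1 vertices; set ``require_leaves=False`` to run the same
    confluent reduction on arbitrary connected graphs (needed for the
    correspondence with GSP graphs, where e.g. a bare triangle shrinks
    to a single edge without ever having had a leaf).
    """
    if graph.number_of_nodes() < 2:
        raise PreconditionError("leaf shrinking needs at least two vertices")
    if require_leaves:
        n_leaves = sum(1 for v in graph.nodes() if graph.degree(v) == 1)
        if n_leaves < 2:
            raise PreconditionError("leaf shrinking needs >= 2 degree-1 vertices")
    if policy not in ("deterministic", "random"):
        raise PreconditionError(f"unknown policy {policy!r}")
    rng = random.Random(seed)

    g = graph.copy()
    trace = ReductionTrace(initial=graph.copy())
    while True:
        ops = applicable_ops(g)
        if not ops:
            break
        op = ops[0] if policy == "deterministic" else rng.choice(ops)
        apply_op(g, op)
        trace.steps.append(op)
    trace.final = g.copy()
    return g, trace


def lcut(network: PhyloNetwork) -> nx.MultiGraph:
    """Leaf cut graph: delete every labeled leaf and its pendant edge.

    New degree-1 or degree-2 vertices that arise are kept.  For the
    degenerate single-edge network (both vertices are leaves) the result
    is the empty graph, flagged via ``graph.graph['lcut_empty']``.
    """
    if network.graph.number_of_nodes() < 2 or len(network.labels) < 2:
        raise PreconditionError("leaf cutting needs |V| >= 2 and |X| >= 2")
    g = network.graph.copy()
    g.remove_nodes_from(network.leaves)
    if g.number_of_nodes() == 0:
        g.graph["lcut_empty"] = True
    return g


def is_restricted_topological_subgraph(graph: nx.MultiGraph,
                                       candidate: nx.MultiGraph,
                                       cap: int = 20000) -> bool:
    """Can ``graph`` be rewritten into something isomorphic to
    ``candidate`` by operations 1-4?

    Breadth-first search over isomorphism classes of reachable states;
    raises :class:`CapExceeded` rather than guessing when the bounded
    state space is exhausted.
    """
    nc, mc = candidate.number_of_nodes(), candidate.number_of_edges()
    visited = IsoSet()
    queue: deque[nx.MultiGraph] = deque()
    visited.add(graph.copy())
    queue.append(graph.copy())
    explored = 0
    while queue:
        state = queue.popleft()
        explored += 1
        if explored > cap:
            raise CapExceeded("is_restricted_topological_subgraph", cap)
        if isomorphic(state, candidate):
            return True
        if state.number_of_nodes() <= nc and state.number_of_edges() <= mc:
            continue  # ops only shrink; nothing below can reach candidate
        for op in _unguarded_ops(state):
            nxt = state.copy()
            apply_op(nxt, op)
            if nxt.number_of_nodes() >= nc and nxt.number_of_edges() >= mc:
                if visited.add(nxt):
                    queue.append(nxt)
    return False


def _unguarded_ops(g: nx.MultiGraph) -> list[RestrictionOp]:
    """All ops 1-4 without the two-vertex guard (the raw definition of
    restricted topological subgraphs has no guard)."""
    ops: list[RestrictionOp] = []
    loops_at = {v for v in g.nodes() if g.number_of_edges(v, v) > 0}
    for v in g.nodes():
        if g.degree(v) == 1:
            ops.append(RestrictionOp(DELETE_LEAF, v))
        elif g.degree(v) == 2 and v not in loops_at and g.number_of_nodes() > 2:
            ops.append(RestrictionOp(SUPPRESS, v))
    seen = set()
    for u, v in g.edges():
        pair = frozenset((u, v))
        if pair in seen:
            continue
        seen.add(pair)
        if u == v:
            ops.append(RestrictionOp(DELETE_LOOP, u))
        elif g.number_of_edges(u, v) >= 2:
            ops.append(RestrictionOp(DELETE_PARALLEL, tuple(sorted((u, v), key=str))))
    return ops
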