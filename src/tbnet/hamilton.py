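"""Exact Hamiltonian path/cycle searches and Hamilton-connectedness.

Backtracking with cheap pruning; exact on the desk-scale graphs this
package handles.  ``None`` from a search means *proven absent*; if the
node budget runs out the search raises :class:`CapExceeded` instead of
guessing, and callers record the indeterminate outcome.

Degenerate conventions: the one-vertex graph and K2 are considered
Hamilton connected (the single vertex / single edge is the path), so
that the leaf-cut characterization of networks that are both edge-based
and H-connected ("single vertex, single edge, or triangle") composes
cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import networkx as nx

from .errors import CapExceeded, PreconditionError
from .graphcore import Vertex, simple_projection


@dataclass
class PathWitness:
    vertices: list
    kind: str  # "path" | "cycle"

    def validate(self, g: nx.MultiGraph) -> bool:
        vs = self.vertices
        if len(set(vs)) != len(vs) or set(vs) != set(g.nodes()):
            return False
        for a, b in zip(vs, vs[1:]):
            if not g.has_edge(a, b):
                return False
        if self.kind == "cycle":
            return len(vs) >= 3 and g.has_edge(vs[-1], vs[0])
        return True


def _backtrack(s: nx.Graph, start: Vertex, target: Optional[Vertex],
               cap: int) -> Optional[list]:
    """Hamiltonian path from start (to target if given, else anywhere)."""
    n = s.number_of_nodes()
    budget = [cap]
    path = [start]
    on_path = {start}

    def extend() -> bool:
        budget[0] -= 1
        if budget[0] < 0:
            raise CapExceeded("hamiltonian search", cap)
        cur = path[-1]
        if len(path) == n:
            return target is None or cur == target
        # prune: a non-endpoint unvisited vertex with < 2 free neighbors,
        # or an unreachable remainder, kills the branch
        for nb in sorted(s.neighbors(cur), key=lambda x: s.degree(x)):
            if nb in on_path:
                continue
            if target is not None and nb == target and len(path) + 1 < n:
                continue
            path.append(nb)
            on_path.add(nb)
            if extend():
                return True
            path.pop()
            on_path.remove(nb)
        return False

    return list(path) if extend() else None


def hamiltonian_path(graph: nx.MultiGraph, u: Vertex, v: Vertex,
                     cap: int = 500000) -> Optional[PathWitness]:
    """Exact search for a Hamiltonian u-v path; None means none exists."""
    if u == v:
        raise PreconditionError("endpoints must differ")
    s = simple_projection(graph)
    if not nx.is_connected(s):
        return None
    if s.number_of_nodes() == 2:
        return PathWitness([u, v], "path") if s.has_edge(u, v) else None
    res = _backtrack(s, u, v, cap)
    return PathWitness(res, "path") if res is not None else None


def hamiltonian_cycle(graph: nx.MultiGraph, cap: int = 500000) -> Optional[PathWitness]:
    """Exact search for a Hamiltonian cycle (graphs with >= 3 vertices)."""
    s = simple_projection(graph)
    if s.number_of_nodes() < 3:
        return None
    if not nx.is_connected(s) or min(d for _, d in s.degree()) < 2:
        return None
    start = min(s.nodes(), key=str)
    # fix the start; try each neighbor as the cycle-closing vertex
    for closer in sorted(s.neighbors(start), key=str):
        res = _path_with_closing(s, start, closer, cap)
        if res is not None:
            return PathWitness(res, "cycle")
    return None


def _path_with_closing(s, start, closer, cap):
    res = _backtrack(s, start, closer, cap)
    return res


def is_hamiltonian(graph: nx.MultiGraph, cap: int = 500000) -> bool:
    return hamiltonian_cycle(graph, cap=cap) is not None


def is_hamilton_connected(graph: nx.MultiGraph, cap: int = 500000) -> bool:
    """Every vertex pair joined by a Hamiltonian path.

    Graphs on at most two vertices are Hamilton connected by
    convention.
    """
    s = simple_projection(graph)
    n = s.number_of_nodes()
    if n <= 2:
        return n == 1 or (n == 2 and s.number_of_edges() == 1)
    if not nx.is_connected(s):
        return False
    for u, v in combinations(sorted(s.nodes(), key=str), 2):
        if hamiltonian_path(s, u, v, cap=cap) is None:
            return False
    return True
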