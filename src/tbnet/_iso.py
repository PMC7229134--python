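"""Isomorphism utilities for small labeled multigraphs.

Reductions and enumeration constantly need to ask "have we seen this
graph before, up to isomorphism?".  Exact canonical forms are overkill
for the desk-scale graphs handled here (typically under a dozen
vertices), so we bucket graphs by a cheap isomorphism invariant and fall
back to networkx's VF2 matcher (which handles parallel edges and loops)
inside each bucket.
"""

from __future__ import annotations

from collections import Counter
from typing import Hashable, Iterable, Iterator, Optional

import networkx as nx

Vertex = Hashable


def multiplicities(g: nx.MultiGraph) -> Counter:
    """Multiset {frozen pair -> number of parallel copies}, loops included."""
    c: Counter = Counter()
    for u, v in g.edges():
        c[frozenset((u, v))] += 1
    return c


def invariant_key(g: nx.MultiGraph, node_attr: Optional[str] = None) -> tuple:
    """A cheap isomorphism-invariant fingerprint used for bucketing.

    When ``node_attr`` is given, per-vertex attribute values enter the
    fingerprint (used e.g. to keep leaf/inner vertices distinguishable).
    """
    degs = sorted(d for _, d in g.degree())
    mults = sorted(multiplicities(g).values())
    loops = sum(1 for u, v in g.edges() if u == v)
    attr_part: tuple = ()
    if node_attr is not None:
        attr_part = tuple(sorted(
            (str(g.nodes[n].get(node_attr)), g.degree(n)) for n in g.nodes()
        ))
    return (g.number_of_nodes(), g.number_of_edges(),
            tuple(degs), tuple(mults), loops, attr_part)


def isomorphic(a: nx.MultiGraph, b: nx.MultiGraph,
               node_attr: Optional[str] = None) -> bool:
    """Multigraph isomorphism (multiplicity- and loop-aware)."""
    if invariant_key(a, node_attr) != invariant_key(b, node_attr):
        return False
    if node_attr is None:
        return nx.is_isomorphic(a, b)
    nm = nx.algorithms.isomorphism.categorical_node_match(node_attr, None)
    return nx.is_isomorphic(a, b, node_match=nm)


class IsoSet:
    """A set of multigraphs modulo isomorphism."""

    def __init__(self, node_attr: Optional[str] = None):
        self._buckets: dict[tuple, list[nx.MultiGraph]] = {}
        self._node_attr = node_attr
        self._n = 0

    def __len__(self) -> int:
        return self._n

    def __iter__(self) -> Iterator[nx.MultiGraph]:
        for bucket in self._buckets.values():
            yield from bucket

    def __contains__(self, g: nx.MultiGraph) -> bool:
        key = invariant_key(g, self._node_attr)
        return any(isomorphic(g, h, self._node_attr)
                   for h in self._buckets.get(key, ()))

    def add(self, g: nx.MultiGraph) -> bool:
        """Insert ``g``; returns True if it was new up to isomorphism."""
        key = invariant_key(g, self._node_attr)
        bucket = self._buckets.setdefault(key, [])
        for h in bucket:
            if isomorphic(g, h, self._node_attr):
                return False
        bucket.append(g)
        self._n += 1
        return True

    def update(self, graphs: Iterable[nx.MultiGraph]) -> None:
        for g in graphs:
            self.add(g)


def graphs_equal(a: nx.MultiGraph, b: nx.MultiGraph) -> bool:
    """Exact equality: same vertex set and same edge multiset (not iso)."""
    return (set(a.nodes()) == set(b.nodes())
            and multiplicities(a) == multiplicities(b))


def is_k2(g: nx.MultiGraph) -> bool:
    """The single-edge graph on two vertices."""
    return (g.number_of_nodes() == 2 and g.number_of_edges() == 1
            and not any(u == v for u, v in g.edges()))
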