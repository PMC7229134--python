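"""Graph substrate and phylogenetic-network validation.

An unrooted phylogenetic network on a taxon set X is a connected simple
graph with no degree-2 vertices whose degree-1 vertices are bijectively
labeled by X.  All reduction machinery in this package operates on
undirected multigraphs (parallel edges and loops allowed), represented
as :class:`networkx.MultiGraph` with opaque string vertex ids; leaf
labels are kept in a separate map so that rewriting never has to touch
label bookkeeping.

This module also provides the two decompositions everything else
consumes: *blocks* (maximal biconnected subgraphs) and *blobs* (maximal
connected subgraphs without a cut edge), together with cut vertices and
cut edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Optional, Union

import networkx as nx

from .errors import NotConnectedError

Vertex = Hashable
Edge = tuple  # (u, v) unordered pair


def simple_projection(g: nx.MultiGraph) -> nx.Graph:
    """Underlying simple graph: parallel copies merged, loops dropped."""
    s = nx.Graph()
    s.add_nodes_from(g.nodes())
    s.add_edges_from((u, v) for u, v in g.edges() if u != v)
    return s


def edge_multiplicity(g: nx.MultiGraph, u: Vertex, v: Vertex) -> int:
    return g.number_of_edges(u, v)


def cut_edges(g: nx.MultiGraph) -> list[Edge]:
    """Cut edges (bridges) of a connected multigraph.

    A parallel pair is never a bridge, and loops never disconnect, so a
    multigraph edge is a cut edge iff it is a bridge of the underlying
    simple graph and has multiplicity 1.
    """
    s = simple_projection(g)
    return [tuple(sorted((u, v), key=str)) for u, v in nx.bridges(s)
            if g.number_of_edges(u, v) == 1]


def cut_vertices(g: nx.MultiGraph) -> set[Vertex]:
    return set(nx.articulation_points(simple_projection(g)))


@dataclass
class PhyloNetwork:
    """A validated unrooted phylogenetic network on taxon set X.

    ``graph`` is simple (stored as a MultiGraph for substrate
    uniformity); ``labels`` maps each taxon label to its degree-1
    vertex.
    """

    graph: nx.MultiGraph
    labels: dict[str, Vertex]

    @property
    def taxa(self) -> set[str]:
        return set(self.labels)

    @property
    def leaves(self) -> set[Vertex]:
        return set(self.labels.values())

    @property
    def leaf_of_label(self) -> dict[str, Vertex]:
        return dict(self.labels)

    @property
    def label_of_leaf(self) -> dict[Vertex, str]:
        return {v: x for x, v in self.labels.items()}

    @property
    def inner_vertices(self) -> set[Vertex]:
        return set(self.graph.nodes()) - self.leaves

    @property
    def inner_edges(self) -> list[Edge]:
        """Edges not incident to a leaf."""
        lv = self.leaves
        return [(u, v) for u, v, _ in self.graph.edges(keys=True)
                if u not in lv and v not in lv]

    @property
    def attachment_points(self) -> dict[str, Vertex]:
        """Label -> the unique neighbor of that leaf."""
        out = {}
        for x, v in self.labels.items():
            out[x] = next(iter(self.graph.neighbors(v)))
        return out

    def is_binary(self) -> bool:
        return all(self.graph.degree(v) == 3 for v in self.inner_vertices)

    def is_tree(self) -> bool:
        return self.graph.number_of_edges() == self.graph.number_of_nodes() - 1

    def copy(self) -> "PhyloNetwork":
        return PhyloNetwork(self.graph.copy(), dict(self.labels))


@dataclass
class Violation:
    code: str
    detail: object = None

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"Violation({self.code}: {self.detail})"


def validate_network(graph: nx.MultiGraph,
                     labels: dict[str, Vertex]) -> Union[PhyloNetwork, list[Violation]]:
    """Check the definition clause by clause.

    Returns a :class:`PhyloNetwork` iff the input is a connected simple
    graph with no degree-2 vertices whose degree-1 vertices carry
    exactly the given labels (bijectively).  Otherwise returns the full
    machine-readable violation list; violations are data, not
    exceptions.
    """
    violations: list[Violation] = []
    g = graph if isinstance(graph, nx.MultiGraph) else nx.MultiGraph(graph)

    if g.number_of_nodes() == 0 or not nx.is_connected(simple_projection(g)):
        violations.append(Violation("not-connected"))
    for u, v in g.edges():
        if u == v:
            violations.append(Violation("loop", u))
            break
    for pair, k in _pair_counts(g).items():
        if k >= 2:
            violations.append(Violation("parallel-edge", tuple(sorted(pair, key=str))))
            break
    for v in g.nodes():
        if g.degree(v) == 2:
            violations.append(Violation("degree-2-vertex", v))

    if not labels:
        violations.append(Violation("empty-taxon-set"))
    degree1 = {v for v in g.nodes() if g.degree(v) == 1}
    labeled = set(labels.values())
    if len(labeled) < len(labels):
        seen: dict[Vertex, str] = {}
        for x, v in labels.items():
            if v in seen:
                violations.append(Violation("duplicate-label", (seen[v], x)))
            seen[v] = x
    for v in degree1 - labeled:
        violations.append(Violation("unlabeled-leaf", v))
    for x, v in labels.items():
        if v not in g.nodes() or g.degree(v) != 1:
            violations.append(Violation("labeled-non-leaf", x))
    if violations:
        return violations
    return PhyloNetwork(g.copy(), dict(labels))


def _pair_counts(g: nx.MultiGraph) -> dict[frozenset, int]:
    out: dict[frozenset, int] = {}
    for u, v in g.edges():
        if u != v:
            key = frozenset((u, v))
            out[key] = out.get(key, 0) + 1
    return out


@dataclass
class Decomposition:
    """Blocks, blobs, cut vertices and cut edges of a connected graph."""

    cut_vertices: list[Vertex]
    cut_edges: list[tuple[Edge, bool]]          # (edge, trivial?)
    blocks: list[tuple[Vertex, ...]]            # vertex subsets, sorted
    blobs: list[tuple[tuple[Vertex, ...], bool]]  # (vertex subset, trivial?)


def decompose(g: nx.MultiGraph) -> Decomposition:
    """Blocks / blobs / cut elements, canonically ordered.

    Blobs are the connected components left after deleting every cut
    edge; a trivial blob is a single vertex.  A cut edge is trivial iff
    one side of its split is a single vertex.
    """
    s = simple_projection(g)
    if g.number_of_nodes() == 0 or not nx.is_connected(s):
        raise NotConnectedError("decompose requires a connected graph")

    cuts = cut_edges(g)
    cut_flagged = []
    for (u, v) in cuts:
        h = g.copy()
        h.remove_edge(u, v)
        comp_u = nx.node_connected_component(simple_projection(h), u)
        comp_v = nx.node_connected_component(simple_projection(h), v)
        trivial = len(comp_u) == 1 or len(comp_v) == 1
        cut_flagged.append(((u, v), trivial))

    blocks = [tuple(sorted(b, key=str)) for b in nx.biconnected_components(s)]
    if g.number_of_nodes() == 1:
        blocks = [tuple(g.nodes())]

    h = g.copy()
    h.remove_edges_from(cuts)
    blobs = []
    for comp in nx.connected_components(simple_projection(h)):
        blobs.append((tuple(sorted(comp, key=str)), len(comp) == 1))

    return Decomposition(
        cut_vertices=sorted(cut_vertices(g), key=str),
        cut_edges=sorted(cut_flagged, key=lambda t: tuple(map(str, t[0]))),
        blocks=sorted(blocks, key=lambda b: tuple(map(str, b))),
        blobs=sorted(blobs, key=lambda b: tuple(map(str, b[0]))),
    )


def blob_subgraph(g: nx.MultiGraph, blob: tuple) -> nx.MultiGraph:
    """Induced subgraph of a blob's vertex set."""
    return nx.MultiGraph(g.subgraph(blob).copy())


def is_proper(network: PhyloNetwork) -> tuple[bool, Optional[dict]]:
    """Properness: removing any cut edge or cut vertex leaves components
    that each contain at least one labeled leaf.

    Returns (True, None) or (False, witness) where the witness names the
    offending cut element and a leafless component.
    """
    g = network.graph
    leaves = network.leaves
    s = simple_projection(g)
    for (u, v) in cut_edges(g):
        s.remove_edge(u, v)
        for comp in nx.connected_components(s):
            if not (comp & leaves):
                s.add_edge(u, v)
                return False, {"cut_element": ("edge", (u, v)),
                               "leafless_component": sorted(comp, key=str)}
        s.add_edge(u, v)
    for v in cut_vertices(g):
        for comp in nx.connected_components(s.subgraph(set(s.nodes()) - {v})):
            if not (comp & leaves):
                return False, {"cut_element": ("vertex", v),
                               "leafless_component": sorted(comp, key=str)}
    return True, None


def is_simple_network(network: PhyloNetwork) -> bool:
    """A simple network has only trivial cut edges."""
    d = decompose(network.graph)
    return all(trivial for _, trivial in d.cut_edges)
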