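"""Fixtures, random generators with ground-truth class labels, and the
exhaustive isomorphism-free enumerator of small proper networks.

Generators come with constructive guarantees:

* ``gen_gsp_network``   -- edge-based by construction (GSP core built
  from two-terminal series / parallel / generalized-series
  compositions of single edges, then leaves attached wherever the core
  degree is below three);
* ``gen_tree_plus_edges`` -- tree-based by construction, returning the
  construction tree as a verifiable support tree;
* ``gen_binary_chordal`` -- binary, chordal and proper by construction
  (blobs grown from a single edge by inverse triangle-collapse steps:
  double an edge, subdivide the new copy; leaves restore degree 3).

The enumerator exhausts, up to isomorphism with exchangeable leaf
labels, every proper network whose inner graph has at most
``max_inner`` vertices and at most ``max_leaves`` leaves.  It powers
the exhaustive verification of the structural theorems on small
networks.
"""

from __future__ import annotations

import itertools
import random
from functools import lru_cache
from typing import Iterator, Union

import networkx as nx

from ._iso import IsoSet
from .errors import PreconditionError
from .graphcore import PhyloNetwork, is_proper, validate_network
from .spgsp import (generalized_series_compose, k2, parallel_compose,
                    series_compose)
from .treebased import SupportTree

KIND = "kind"  # node attribute used for leaf/inner-aware isomorphism


# ---------------------------------------------------------------------------
# Fixtures

def fixture(name: str) -> Union[PhyloNetwork, nx.MultiGraph]:
    """Built-in test networks and graphs.

    ``FIX-A``: a triangle w,p,q with a pendant inner vertex s on w;
    leaves 1,2 attach to s, leaf 3 to p, leaf 4 to q.  Binary, proper,
    edge-based; its leaf cut graph has one unlabeled leaf.

    ``FIX-B``: K4 with leaves 1 and 2 on two of its vertices.
    Tree-based (its K4 core is Hamilton connected) but not edge-based.
    """
    if name == "FIX-A":
        g = nx.MultiGraph()
        g.add_edges_from([("w", "p"), ("w", "q"), ("p", "q"), ("s", "w"),
                          ("s", "1"), ("s", "2"), ("p", "3"), ("q", "4")])
        return _net(g, {"1": "1", "2": "2", "3": "3", "4": "4"})
    if name == "FIX-B":
        g = nx.MultiGraph()
        g.add_edges_from([("u", "v"), ("u", "w1"), ("u", "w2"), ("v", "w1"),
                          ("v", "w2"), ("w1", "w2"), ("u", "1"), ("v", "2")])
        return _net(g, {"1": "1", "2": "2"})
    if name == "petersen":
        return nx.MultiGraph(nx.relabel_nodes(nx.petersen_graph(),
                                              {i: f"p{i}" for i in range(10)}))
    if name == "double-star":
        g = nx.MultiGraph()
        g.add_edges_from([("a", "b"), ("a", "1"), ("a", "2"),
                          ("b", "3"), ("b", "4")])
        return _net(g, {"1": "1", "2": "2", "3": "3", "4": "4"})
    if name == "single-edge":
        g = nx.MultiGraph()
        g.add_edge("1", "2")
        return _net(g, {"1": "1", "2": "2"})
    if name == "triangle-leaves":
        g = nx.MultiGraph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("a", "1"), ("b", "2"), ("c", "3")])
        return _net(g, {"1": "1", "2": "2", "3": "3"})
    raise KeyError(f"unknown fixture {name!r}")


def _net(g: nx.MultiGraph, labels: dict) -> PhyloNetwork:
    res = validate_network(g, labels)
    if not isinstance(res, PhyloNetwork):  # pragma: no cover
        raise AssertionError(f"fixture invalid: {res}")
    return res


# ---------------------------------------------------------------------------
# Random generators

def random_connected_multigraph(rng: random.Random, n_max: int = 10,
                                extra_parallel: int = 2, loops: bool = True,
                                require_leaves: bool = False) -> nx.MultiGraph:
    """Random connected multigraph (tree backbone plus random extra
    edges, parallel copies and loops); the raw substrate for confluence
    and invariance checks."""
    n = rng.randint(2, n_max)
    g = nx.MultiGraph()
    g.add_node(0)
    for v in range(1, n):
        g.add_edge(v, rng.randrange(v))
    for _ in range(rng.randint(0, n)):
        u, v = rng.randrange(n), rng.randrange(n)
        if u != v:
            g.add_edge(u, v)
    for _ in range(rng.randint(0, extra_parallel)):
        u, v, _k = rng.choice(sorted(g.edges(keys=True)))
        if u != v:
            g.add_edge(u, v)
    if loops and rng.random() < 0.4:
        u, v = rng.randrange(n), rng.randrange(n)
        if u != v:
            g.add_edge(u, v)
    if loops and rng.random() < 0.3:
        v = rng.randrange(n)
        g.add_edge(v, v)
    if require_leaves:
        for i in range(2):
            g.add_edge(n + i, rng.randrange(n))
    return g


def random_loopless_simple_graph(rng: random.Random,
                                 n_max: int = 10) -> nx.MultiGraph:
    """Random connected simple loopless graph (tree plus extra edges)."""
    n = rng.randint(2, n_max)
    g = nx.Graph()
    g.add_node(0)
    for v in range(1, n):
        g.add_edge(v, rng.randrange(v))
    candidates = [(u, v) for u, v in itertools.combinations(range(n), 2)
                  if not g.has_edge(u, v)]
    rng.shuffle(candidates)
    for e in candidates[:rng.randint(0, n)]:
        g.add_edge(*e)
    return nx.MultiGraph(g)


def _attach_leaves(core: nx.MultiGraph) -> PhyloNetwork:
    """Attach labeled leaves so every core vertex reaches degree >= 3."""
    g = core.copy()
    labels = {}
    i = 1
    for v in sorted(core.nodes(), key=str):
        need = max(0, 3 - core.degree(v))
        for _ in range(need):
            leaf = f"x{i}"
            g.add_edge(v, leaf)
            labels[str(i)] = leaf
            i += 1
    return _net(g, labels)


def gen_gsp_network(n_ops: int = 6, seed: int = 0,
                    allow_generalized: bool = True) -> PhyloNetwork:
    """Random edge-based proper network from a GSP composition core."""
    rng = random.Random(seed)
    g, t = k2("u0", "v0")
    for i in range(n_ops):
        h, s = k2(f"u{i + 1}", f"v{i + 1}")
        ops = [series_compose, parallel_compose]
        if allow_generalized:
            ops.append(generalized_series_compose)
        g, t = rng.choice(ops)(g, t, h, s)
    core = nx.MultiGraph()
    core.add_nodes_from(g.nodes())
    core.add_edges_from({tuple(sorted(e, key=str)) for e in g.edges()})
    net = _attach_leaves(core)
    assert is_proper(net)[0], "GSP generator produced an improper network"
    return net


def gen_tree_plus_edges(n_leaves: int, k_extra: int,
                        seed: int = 0) -> tuple[PhyloNetwork, SupportTree]:
    """Random tree plus ``k_extra`` cross edges between subdivided tree
    edges; the construction tree is returned as a known support tree."""
    if n_leaves < 2:
        raise PreconditionError("need at least two leaves")
    if k_extra > 0 and n_leaves < 3:
        raise PreconditionError("cross edges need a tree with >= 2 edges")
    rng = random.Random(seed)
    tree = nx.Graph()
    labels = {}
    if n_leaves == 2:
        tree.add_edge("x1", "x2")
        labels = {"1": "x1", "2": "x2"}
    else:
        tree.add_edges_from([("i0", "x1"), ("i0", "x2"), ("i0", "x3")])
        labels = {"1": "x1", "2": "x2", "3": "x3"}
        for j in range(4, n_leaves + 1):
            u, v = rng.choice(sorted(tree.edges(), key=str))
            w = f"i{j - 3}"
            tree.remove_edge(u, v)
            tree.add_edges_from([(u, w), (w, v), (w, f"x{j}")])
            labels[str(j)] = f"x{j}"

    net_g = nx.MultiGraph(tree)
    support = nx.Graph(tree)
    for j in range(k_extra):
        e1, e2 = rng.sample(sorted(support.edges(), key=str), 2)
        a, b = f"s{2 * j}", f"s{2 * j + 1}"
        for (u, v), w in ((e1, a), (e2, b)):
            for h in (net_g, support):
                h.remove_edge(u, v)
                h.add_edges_from([(u, w), (w, v)])
        net_g.add_edge(a, b)  # cross edge: in the network, not the tree
    net = _net(net_g, labels)
    st = SupportTree(support, dict(labels))
    assert st.validate(net), "construction tree is not a support tree"
    return net, st


def _grow_blob(rng: random.Random, steps: int, tag: str) -> nx.MultiGraph:
    """Inverse triangle-collapse growth from a single edge: pick an edge
    whose endpoints both have degree <= 2, add a parallel copy and
    subdivide it.  Chordality is invariant (the new vertex is
    simplicial); max degree stays <= 3."""
    g = nx.MultiGraph()
    g.add_edge(f"{tag}0", f"{tag}1")
    nxt = 2
    for _ in range(steps):
        eligible = sorted({tuple(sorted((u, v), key=str)) for u, v in g.edges()
                           if g.degree(u) <= 2 and g.degree(v) <= 2})
        if not eligible:
            break
        u, v = rng.choice(eligible)
        w = f"{tag}{nxt}"
        nxt += 1
        g.add_edges_from([(u, w), (w, v)])
    return g


def gen_binary_chordal(n_blobs: int = 2, blob_steps: int = 2,
                       seed: int = 0) -> PhyloNetwork:
    """Random proper binary chordal network: a binary backbone tree in
    which some leaves are replaced by blobs grown via inverse
    triangle-collapse steps; leaves restore inner degree 3.

    ``n_blobs = 0`` (or zero growth steps everywhere) yields a tree.
    """
    rng = random.Random(seed)
    n_backbone = max(3, n_blobs + 2)
    tree, labels = _random_binary_tree(rng, n_backbone)
    g = nx.MultiGraph(tree)
    replaced = rng.sample(sorted(labels), min(n_blobs, len(labels) - 2))
    for bi, lab in enumerate(replaced):
        leaf = labels.pop(lab)
        u = next(iter(g.neighbors(leaf)))
        g.remove_node(leaf)
        steps = rng.randint(1, max(1, blob_steps))
        blob = _grow_blob(rng, steps, tag=f"b{bi}_")
        g.add_edges_from(blob.edges())
        anchor = min((v for v in blob.nodes() if blob.degree(v) <= 2), key=str)
        g.add_edge(u, anchor)
    # attach fresh leaves wherever degree dropped below 3
    i = max((int(x) for x in labels), default=0)
    for v in sorted([n for n in g.nodes()
                     if n not in labels.values() and g.degree(n) < 3], key=str):
        while g.degree(v) < 3:
            i += 1
            g.add_edge(v, f"x{i}")
            labels[str(i)] = f"x{i}"
    net = _net(g, labels)
    assert net.is_binary()
    assert is_proper(net)[0]
    return net


def _random_binary_tree(rng: random.Random, n_leaves: int):
    tree = nx.Graph([("i0", "x1"), ("i0", "x2"), ("i0", "x3")])
    labels = {"1": "x1", "2": "x2", "3": "x3"}
    for j in range(4, n_leaves + 1):
        u, v = rng.choice(sorted(tree.edges(), key=str))
        w = f"i{j - 3}"
        tree.remove_edge(u, v)
        tree.add_edges_from([(u, w), (w, v), (w, f"x{j}")])
        labels[str(j)] = f"x{j}"
    return tree, labels


# ---------------------------------------------------------------------------
# Exhaustive enumeration of small proper networks

@lru_cache(maxsize=None)
def _connected_graphs(n: int) -> tuple:
    """All connected simple graphs on n vertices, up to isomorphism
    (from the networkx graph atlas, which covers up to 7 vertices)."""
    from networkx.generators.atlas import graph_atlas_g
    out = []
    for g in graph_atlas_g():
        if g.number_of_nodes() == n and n >= 1 and nx.is_connected(g):
            out.append(nx.convert_node_labels_to_integers(g))
    return tuple(out)


def _naive_connected_graphs(n: int) -> tuple:
    """Independent edge-subset enumeration (cross-check for the atlas
    route; desk-scale n only)."""
    if n == 1:
        g = nx.Graph()
        g.add_node(0)
        return (g,)
    pairs = list(itertools.combinations(range(n), 2))
    seen = IsoSet()
    out = []
    for bits in range(1 << len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(p for i, p in enumerate(pairs) if bits >> i & 1)
        if nx.is_connected(g) and seen.add(nx.MultiGraph(g)):
            out.append(g)
    return tuple(out)


def enumerate_networks(max_inner: int, max_leaves: int,
                       require_proper: bool = True) -> Iterator[PhyloNetwork]:
    """Yield, up to isomorphism (leaf labels exchangeable), every proper
    network whose inner graph has <= max_inner vertices and that has
    <= max_leaves leaves."""
    if max_inner > 7:
        raise PreconditionError("enumeration is desk-scale: max_inner <= 7")
    if max_leaves >= 2:
        net = fixture("single-edge")
        _mark(net)
        yield net
    for n in range(1, max_inner + 1):
        for inner in _connected_graphs(n):
            # the inner graph (all non-leaf vertices) is an isomorphism
            # invariant of the network, so dedup only within one inner
            # graph's leaf distributions
            seen = IsoSet(node_attr=KIND)
            req = [max(0, 3 - inner.degree(v)) for v in range(n)]
            if sum(req) > max_leaves:
                continue
            auts = _automorphisms(inner)
            for counts in _leaf_distributions(req, max_leaves):
                if sum(counts) == 0:
                    continue  # a network needs at least one taxon
                # one representative per automorphism orbit of the
                # leaf-count vector: permuted vectors give isomorphic
                # networks
                if any(tuple(counts[p[v]] for v in range(n)) > counts
                       for p in auts):
                    continue
                g = nx.MultiGraph()
                g.add_nodes_from(range(n))
                g.add_edges_from(inner.edges())
                labels = {}
                li = 0
                for v in range(n):
                    for _ in range(counts[v]):
                        li += 1
                        g.add_edge(v, f"x{li}")
                        labels[str(li)] = f"x{li}"
                res = validate_network(g, labels)
                if not isinstance(res, PhyloNetwork):
                    continue
                if require_proper and not is_proper(res)[0]:
                    continue
                _mark(res)
                if seen.add(res.graph):
                    yield res


def _automorphisms(g: nx.Graph) -> list[dict]:
    gm = nx.algorithms.isomorphism.GraphMatcher(g, g)
    return list(gm.isomorphisms_iter())


def _mark(net: PhyloNetwork) -> None:
    leaves = net.leaves
    for v in net.graph.nodes():
        net.graph.nodes[v][KIND] = "leaf" if v in leaves else "inner"


def _leaf_distributions(req: list[int], max_total: int) -> Iterator[tuple]:
    """All per-vertex leaf counts with counts[v] >= req[v] and a bounded
    total."""
    n = len(req)

    def rec(i: int, left: int):
        if i == n:
            yield ()
            return
        for c in range(req[i], left - sum(req[i + 1:]) + 1):
            for rest in rec(i + 1, left - c):
                yield (c,) + rest

    yield from rec(0, max_total)
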