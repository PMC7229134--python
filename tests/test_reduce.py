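import random

import networkx as nx
import pytest

from tbnet import (applicable_ops, fixture, is_restricted_topological_subgraph,
                   lcut, leaf_shrink)
from tbnet._iso import is_k2, isomorphic
from tbnet.errors import PreconditionError
from tbnet.reduce import (DELETE_LOOP, DELETE_PARALLEL, SUPPRESS,
                          RestrictionOp, apply_op)

from conftest import random_connected_multigraph


def K4():
    return nx.MultiGraph([("a", "b"), ("a", "c"), ("a", "d"),
                          ("b", "c"), ("b", "d"), ("c", "d")])


def triangle():
    return nx.MultiGraph([("a", "b"), ("b", "c"), ("a", "c")])


class TestLcut:
    def test_fix_a_leaves_triangle_with_new_leaf(self, fix_a):
        g = lcut(fix_a)
        assert sorted(g.nodes()) == ["p", "q", "s", "w"]
        assert g.number_of_edges() == 4
        # the pendant vertex s becomes a new leaf not labeled by X
        assert g.degree("s") == 1

    def test_double_star_reduces_to_k2(self):
        assert is_k2(lcut(fixture("double-star")))

    def test_single_edge_gives_flagged_empty_graph(self):
        g = lcut(fixture("single-edge"))
        assert g.number_of_nodes() == 0
        assert g.graph.get("lcut_empty") is True


class TestApplicableOps:
    def test_k4_has_no_ops(self):
        assert applicable_ops(K4()) == []

    def test_triangle_offers_three_suppressions(self):
        ops = applicable_ops(triangle())
        assert len(ops) == 3
        assert all(op.kind == SUPPRESS for op in ops)

    def test_two_vertex_guard_restricts_to_edge_deletions(self):
        g = nx.MultiGraph([("u", "v"), ("u", "v")])
        ops = applicable_ops(g)
        assert [op.kind for op in ops] == [DELETE_PARALLEL]
        g.add_edge("u", "u")
        kinds = {op.kind for op in applicable_ops(g)}
        assert kinds == {DELETE_PARALLEL, DELETE_LOOP}


class TestLeafShrink:
    def test_fix_a_shrinks_to_k2(self, fix_a):
        ls, trace = leaf_shrink(fix_a.graph)
        assert is_k2(ls)
        assert trace.verify()

    def test_fix_b_shrinks_to_k4(self, fix_b):
        ls, _ = leaf_shrink(fix_b.graph)
        assert isomorphic(ls, K4())

    def test_tree_shrinks_to_k2(self):
        tree = nx.MultiGraph(nx.random_labeled_tree(9, seed=4))
        ls, _ = leaf_shrink(tree)
        assert is_k2(ls)

    def test_preconditions(self):
        with pytest.raises(PreconditionError):
            leaf_shrink(nx.MultiGraph([("a", "a")]))  # one vertex
        with pytest.raises(PreconditionError):
            leaf_shrink(triangle())  # no leaves under the strict contract

    def test_trace_replays_bit_exactly(self):
        rng = random.Random(11)
        for _ in range(50):
            g = random_connected_multigraph(rng, n_max=8, require_leaves=True)
            _, trace = leaf_shrink(g, policy="random", seed=rng.randrange(999))
            assert trace.verify()
            replay = trace.replay()
            assert set(replay.nodes()) == set(trace.final.nodes())

    def test_confluence_across_policies(self):
        rng = random.Random(3)
        for _ in range(60):
            g = random_connected_multigraph(rng, n_max=9)
            results = [leaf_shrink(g, policy="random", seed=s,
                                   require_leaves=False)[0] for s in range(4)]
            results.append(leaf_shrink(g, require_leaves=False)[0])
            assert all(isomorphic(results[0], r) for r in results[1:])


class TestLsInvariance:
    """Adding or removing decorations never changes LS(G) up to iso."""

    def _ls(self, g):
        return leaf_shrink(g, require_leaves=False)[0]

    def test_additions_preserve_ls(self):
        rng = random.Random(5)
        for _ in range(100):
            g = random_connected_multigraph(rng, n_max=8)
            base = self._ls(g)
            v = rng.choice(sorted(g.nodes(), key=str))
            g1 = g.copy()
            g1.add_edge(v, "fresh-leaf")
            g2 = g.copy()
            u, w, _k = rng.choice(sorted(g2.edges(keys=True)))
            g2.remove_edge(u, w)
            g2.add_edges_from([(u, "mid"), ("mid", w)])
            g3 = g.copy()
            g3.add_edge(u, w)
            g4 = g.copy()
            g4.add_edge(v, v)
            for variant in (g1, g2, g3, g4):
                assert isomorphic(self._ls(variant), base)

    def test_deletions_of_copies_preserve_ls(self):
        rng = random.Random(6)
        done = 0
        while done < 100:
            g = random_connected_multigraph(rng, n_max=8)
            base = self._ls(g)
            loops = [(u, v) for u, v in g.edges() if u == v]
            parallels = sorted({(u, v) for u, v in g.edges()
                                if u != v and g.number_of_edges(u, v) >= 2})
            if not loops and not parallels:
                continue
            h = g.copy()
            if loops:
                h.remove_edge(*loops[0])
            else:
                h.remove_edge(*parallels[0])
            assert isomorphic(self._ls(h), base)
            done += 1

    def test_ls_equals_ls_of_underlying_simple_graph(self):
        rng = random.Random(8)
        for _ in range(100):
            g = random_connected_multigraph(rng, n_max=8)
            simple = nx.MultiGraph()
            simple.add_nodes_from(g.nodes())
            simple.add_edges_from({tuple(sorted((u, v), key=str))
                                   for u, v in g.edges() if u != v})
            assert isomorphic(self._ls(g), self._ls(simple))


class TestRestrictedTopologicalSubgraph:
    def test_fix_a_graph_reaches_k2(self, fix_a):
        assert is_restricted_topological_subgraph(fix_a.graph,
                                                  nx.MultiGraph([("x", "y")]))

    def test_k4_never_reaches_k2(self):
        assert not is_restricted_topological_subgraph(
            K4(), nx.MultiGraph([("x", "y")]))

    def test_reflexive(self, fix_b):
        assert is_restricted_topological_subgraph(fix_b.graph, fix_b.graph)


from hypothesis import given, settings
from hypothesis import strategies as st


@st.composite
def connected_multigraphs(draw):
    n = draw(st.integers(2, 8))
    g = nx.MultiGraph()
    g.add_node(0)
    for v in range(1, n):
        g.add_edge(v, draw(st.integers(0, v - 1)))
    for u, v in draw(st.lists(st.tuples(st.integers(0, n - 1),
                                        st.integers(0, n - 1)), max_size=6)):
        g.add_edge(u, v)  # parallels and loops welcome
    return g


@settings(max_examples=60, derandomize=True, deadline=None)
@given(connected_multigraphs())
def test_leaf_shrink_reaches_a_fixed_point(g):
    """LS output admits no further restriction operation, is simple,
    and the trace replays; degree sums stay consistent throughout."""
    assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()
    ls, trace = leaf_shrink(g, require_leaves=False)
    assert applicable_ops(ls) == []
    assert not any(u == v for u, v in ls.edges())
    assert all(ls.number_of_edges(u, v) == 1 for u, v in ls.edges())
    assert trace.verify()


def test_apply_op_validates_preconditions():
    g = triangle()
    with pytest.raises(PreconditionError):
        apply_op(g, RestrictionOp("delete-leaf", "a"))
    with pytest.raises(PreconditionError):
        apply_op(g, RestrictionOp(DELETE_PARALLEL, ("a", "b")))
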