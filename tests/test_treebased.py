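import math
import random
from fractions import Fraction

import networkx as nx
import pytest

from tbnet import (chordal_binary_reduction, classify,
                   criterion_h_connected, criterion_lcon_gadget,
                   criterion_lcon_new_edge, criterion_path,
                   criterion_tough_chordal, fixture, is_chordal,
                   is_tree_based_oracle, support_tree_edge_based, toughness,
                   valid_spanning_tree, validate_network)
from tbnet._iso import is_k2
from tbnet.errors import PreconditionError
from tbnet.graphcore import decompose
from tbnet.synth import gen_binary_chordal, gen_gsp_network, gen_tree_plus_edges


class TestOracle:
    def test_fix_a_with_witness(self, fix_a):
        ok, st = is_tree_based_oracle(fix_a)
        assert ok and st.validate(fix_a)

    def test_single_edge_trivially_tree_based(self):
        ok, st = is_tree_based_oracle(fixture("single-edge"))
        assert ok and st.validate(fixture("single-edge"))

    def test_fix_b(self, fix_b):
        assert is_tree_based_oracle(fix_b)[0]

    def test_non_tree_based_network_exists(self):
        # smallest cases need 6 inner vertices; found by exhaustive search
        g = nx.MultiGraph([("a", "b"), ("a", "d"), ("a", "f"), ("b", "c"),
                           ("b", "e"), ("c", "d"), ("c", "f"), ("d", "e"),
                           ("e", "f"), ("a", "x1"), ("c", "x2")])
        net = validate_network(g, {"1": "x1", "2": "x2"})
        from tbnet import is_proper
        assert is_proper(net)[0]
        assert not is_tree_based_oracle(net)[0]


class TestSupportTreeConstruction:
    def test_fix_a_seven_edges_leaves_x(self, fix_a):
        st = support_tree_edge_based(fix_a)
        assert len(st.edges()) == 7
        t = st.tree
        assert {v for v in t.nodes() if t.degree(v) == 1} == {"1", "2", "3", "4"}

    def test_tree_network_is_its_own_support_tree(self):
        net = fixture("double-star")
        st = support_tree_edge_based(net)
        assert set(map(frozenset, st.tree.edges())) == \
            set(frozenset((u, v)) for u, v in net.graph.edges())

    def test_two_blob_network(self):
        g = nx.MultiGraph([("a", "b"), ("b", "c"), ("a", "c"),
                           ("d", "e"), ("e", "f"), ("d", "f"),
                           ("a", "d"),
                           ("b", "x1"), ("c", "x2"), ("e", "x3"), ("f", "x4")])
        net = validate_network(g, {str(i): f"x{i}" for i in range(1, 5)})
        st = support_tree_edge_based(net)
        assert st.validate(net)
        base, labels = st.base_tree()
        assert {v for v in base.nodes() if base.degree(v) == 1} == set(labels.values())

    def test_non_edge_based_rejected(self, fix_b):
        with pytest.raises(PreconditionError):
            support_tree_edge_based(fix_b)

    def test_theorem3_on_generated_networks(self):
        rng = random.Random(41)
        for _ in range(40):
            net = gen_gsp_network(n_ops=rng.randint(2, 6), seed=rng.randrange(10**6))
            st = support_tree_edge_based(net)
            assert st.validate(net)
            assert is_tree_based_oracle(net)[0]


class TestValidSpanningTree:
    def test_triangle_any_two_edge_path(self):
        tri = nx.MultiGraph([("a", "b"), ("b", "c"), ("a", "c")])
        t = valid_spanning_tree(tri)
        assert nx.is_tree(t) and t.number_of_edges() == 2

    def test_diamond_leaves_are_the_degree2_vertices(self):
        dia = nx.MultiGraph([("a", "b"), ("a", "c"), ("a", "d"),
                             ("b", "c"), ("b", "d")])  # c, d have degree 2
        t = valid_spanning_tree(dia)
        leaves = {v for v in t.nodes() if t.degree(v) == 1}
        assert leaves <= {"c", "d"}

    def test_k2(self):
        t = valid_spanning_tree(nx.MultiGraph([("u", "v")]))
        assert sorted(t.edges()) == [("u", "v")]

    def test_non_sp_block_rejected(self):
        k4 = nx.MultiGraph([(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)])
        with pytest.raises(PreconditionError):
            valid_spanning_tree(k4)

    def test_lemma5_on_sp_blocks_of_generated_networks(self):
        rng = random.Random(42)
        for _ in range(25):
            net = gen_gsp_network(n_ops=rng.randint(3, 6), seed=rng.randrange(10**6))
            d = decompose(net.graph)
            for bvs in d.blocks:
                if len(bvs) < 3:
                    continue
                block = nx.MultiGraph(net.graph.subgraph(bvs).copy())
                t = valid_spanning_tree(block)
                for v in t.nodes():
                    if t.degree(v) == 1:
                        assert block.degree(v) == 2


class TestCriteria:
    def test_criterion1(self, fix_a, fix_b):
        assert criterion_path(fix_b)[0]
        assert not criterion_path(fix_a)[0]
        assert not criterion_path(fixture("single-edge"))[0]

    def test_criterion2(self, fix_a, fix_b):
        assert not criterion_h_connected(fix_a)
        assert criterion_h_connected(fix_b)
        assert criterion_h_connected(fixture("double-star"))  # LCUT = K2

    def test_criterion3(self, fix_a, fix_b):
        ok, wit = criterion_lcon_new_edge(fix_a)
        assert ok and wit["cycle"].validate(wit["graph"].graph)
        assert criterion_lcon_new_edge(fix_b)[0]

    def test_criterion4(self, fix_a, fix_b):
        assert criterion_lcon_gadget(fix_b)[0]
        assert criterion_lcon_gadget(fix_a)[0]

    def test_criterion4_false_without_gadgets(self):
        # two stacked triangles with leaves on non-adjacent attachment
        # points: the single pair join is never parallel, so the gadget
        # criterion stays false even though a Hamiltonian member exists
        g = nx.MultiGraph([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"),
                           ("c", "d"), ("b", "x1"), ("d", "x2")])
        net = validate_network(g, {"1": "x1", "2": "x2"})
        from tbnet import lcon
        res = lcon(net)
        assert all(not ann.pair_gadget_vertices for ann in res.graphs)
        assert not criterion_lcon_gadget(net)[0]
        assert criterion_lcon_new_edge(net)[0]


class TestChordal:
    def test_examples(self, fix_a):
        assert is_chordal(nx.MultiGraph([(1, 2), (2, 3), (1, 3)]))
        assert not is_chordal(nx.MultiGraph([(1, 2), (2, 3), (3, 4), (4, 1)]))
        assert is_chordal(fix_a.graph)

    def test_multigraph_rejected(self):
        g = nx.MultiGraph([(1, 2), (1, 2), (2, 3), (1, 3)])
        with pytest.raises(PreconditionError):
            is_chordal(g)


class TestChordalBinaryReduction:
    def test_fix_a_trace_ends_in_k2(self, fix_a):
        tr = chordal_binary_reduction(fix_a)
        assert tr.verify() and is_k2(tr.final)

    def test_two_triangle_network(self):
        net = gen_binary_chordal(n_blobs=2, blob_steps=2, seed=5)
        tr = chordal_binary_reduction(net)
        assert tr.verify() and is_k2(tr.final)

    def test_non_chordal_rejected(self):
        g = nx.MultiGraph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"),
                           ("a", "1"), ("b", "2"), ("c", "3"), ("d", "4")])
        net = validate_network(g, {str(i): str(i) for i in range(1, 5)})
        with pytest.raises(PreconditionError, match="not-chordal"):
            chordal_binary_reduction(net)


class TestToughness:
    def test_examples(self):
        assert toughness(nx.MultiGraph([(1, 2), (2, 3), (3, 4), (4, 1)])) == 1
        assert toughness(nx.MultiGraph([(1, 2), (2, 3)])) == Fraction(1, 2)
        k4 = nx.MultiGraph([(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)])
        assert toughness(k4) == math.inf


class TestToughChordalCriterion:
    def test_fix_a_true(self, fix_a):
        # LCUT(FIX-A) has a degree-1 vertex, hence no Hamiltonian cycle;
        # its sole leaf-connect graph K4 is chordal with infinite toughness
        assert criterion_tough_chordal(fix_a)

    def test_hamiltonian_lcut_short_circuits(self, fix_b):
        assert not criterion_tough_chordal(fix_b)


class TestClassify:
    def test_fix_a_report(self, fix_a):
        rep = classify(fix_a)
        assert (rep.proper, rep.binary, rep.chordal) == (True, True, True)
        assert rep.edge_based and rep.tree_based
        assert rep.h_connected is False
        assert rep.tree_based_method == "edge-based"
        assert rep.witnesses["support_tree"].validate(fix_a)
        assert rep.to_json()["edge_based"] is True

    def test_fix_b_report(self, fix_b):
        rep = classify(fix_b)
        assert not rep.edge_based
        assert rep.h_connected and rep.tree_based
        assert not rep.caps_hit

    def test_single_edge_trivially_tree_based(self):
        rep = classify(fixture("single-edge"))
        assert rep.tree_based and rep.tree_based_method in ("trivial", "edge-based")

    def test_sufficient_flags_force_tree_based(self, small_networks):
        rng = random.Random(43)
        for net in rng.sample(small_networks, 60):
            rep = classify(net)
            if rep.edge_based or rep.h_connected:
                assert rep.tree_based


class TestConverses:
    def test_tree_based_but_not_edge_based(self, fix_b):
        assert is_tree_based_oracle(fix_b)[0]
        from tbnet import is_edge_based
        assert not is_edge_based(fix_b)[0]

    def test_chordal_proper_nonbinary_non_tree_based_exists(self):
        """Chordality alone does not imply tree-basedness: a non-binary
        chordal proper counterexample (found by exhaustive search)."""
        g = nx.MultiGraph([("a", "b"), ("a", "c"), ("a", "f"), ("b", "c"),
                           ("b", "d"), ("b", "e"), ("b", "f"), ("c", "f"),
                           ("d", "e"), ("d", "f"), ("e", "f"),
                           ("b", "x1"), ("f", "x2")])
        net = validate_network(g, {"1": "x1", "2": "x2"})
        from tbnet import is_proper
        assert is_proper(net)[0]
        assert is_chordal(net.graph) and not net.is_binary()
        assert not is_tree_based_oracle(net)[0]

    def test_theorem6_on_generated_binary_chordal(self):
        from tbnet import is_edge_based
        rng = random.Random(44)
        for _ in range(25):
            net = gen_binary_chordal(n_blobs=rng.randint(0, 3),
                                     blob_steps=rng.randint(1, 3),
                                     seed=rng.randrange(10**6))
            assert net.is_binary() and is_chordal(net.graph)
            assert is_edge_based(net)[0]


def test_tree_plus_edges_support_tree_verifies():
    rng = random.Random(45)
    for _ in range(25):
        net, st = gen_tree_plus_edges(rng.randint(3, 6), rng.randint(0, 2),
                                      seed=rng.randrange(10**6))
        assert st.validate(net)
        assert is_tree_based_oracle(net)[0]
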