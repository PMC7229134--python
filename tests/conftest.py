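import itertools

import networkx as nx
import pytest

from tbnet import enumerate_networks, fixture


@pytest.fixture(scope="session")
def fix_a():
    return fixture("FIX-A")


@pytest.fixture(scope="session")
def fix_b():
    return fixture("FIX-B")


@pytest.fixture(scope="session")
def petersen():
    return fixture("petersen")


@pytest.fixture(scope="session")
def small_networks():
    """Exhaustive proper networks, <=5 inner vertices, <=6 leaves."""
    return list(enumerate_networks(5, 6))


from tbnet.synth import (random_connected_multigraph,  # noqa: F401
                         random_loopless_simple_graph)


def brute_force_hamiltonian_path(g: nx.MultiGraph, u, v) -> bool:
    """Independent permutation brute force (<= 8 vertices)."""
    s = nx.Graph((a, b) for a, b in g.edges() if a != b)
    s.add_nodes_from(g.nodes())
    nodes = [x for x in s.nodes() if x not in (u, v)]
    for perm in itertools.permutations(nodes):
        seq = [u, *perm, v]
        if all(s.has_edge(a, b) for a, b in zip(seq, seq[1:])):
            return True
    return False


def brute_force_hamiltonian_cycle(g: nx.MultiGraph) -> bool:
    s = nx.Graph((a, b) for a, b in g.edges() if a != b)
    s.add_nodes_from(g.nodes())
    if s.number_of_nodes() < 3:
        return False
    start, *rest = sorted(s.nodes(), key=str)
    for perm in itertools.permutations(rest):
        seq = [start, *perm]
        if s.has_edge(seq[-1], seq[0]) and \
                all(s.has_edge(a, b) for a, b in zip(seq, seq[1:])):
            return True
    return False
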