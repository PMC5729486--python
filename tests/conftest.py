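import networkx as nx
import pytest

from necknet import (
    generate_network,
    generate_tree,
    load_neck_parameters,
    read_tree,
)


@pytest.fixture(scope="session")
def table2():
    """The published 48-species x 7-parameter table."""
    return load_neck_parameters()


@pytest.fixture(scope="session")
def two_cliques_bridge():
    """Two 3-cliques joined by one edge: the classic modular toy graph."""
    g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    g.add_edge(0, 3)
    return g


@pytest.fixture(scope="session")
def two_four_cliques():
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g.add_edge(0, 4)
    return g


@pytest.fixture(scope="session")
def neck_network():
    return generate_network(seed=11)


@pytest.fixture(scope="session")
def tree48():
    return generate_tree(48, seed=7)


@pytest.fixture(scope="session")
def balanced8():
    """Balanced ultrametric 8-tip tree with unit-depth structure."""
    nwk = ("((((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1):0);")
    return read_tree(nwk)


def random_connected_graph(rng, n_max=40):
    """A connected simple random graph with 4..n_max nodes."""
    n = int(rng.integers(4, n_max + 1))
    p = rng.uniform(0.1, 0.6)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return g
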