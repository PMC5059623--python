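import networkx as nx
import numpy as np
import pytest

from diffmod import Interactome, normalize_adjacency


@pytest.fixture
def path3():
    """Path A - B - C."""
    return Interactome([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle():
    return Interactome([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4():
    """Hub H with three leaves."""
    return Interactome([("H", "L1"), ("H", "L2"), ("H", "L3")])


@pytest.fixture
def k2():
    return Interactome([("A", "B")])


def random_interactome(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return Interactome.from_networkx(
        nx.relabel_nodes(g, {i: f"g{i:03d}" for i in g.nodes()})
    )


@pytest.fixture
def random_net():
    return random_interactome(50, 0.1, seed=7)


@pytest.fixture
def W_path3(path3):
    return normalize_adjacency(path3)
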