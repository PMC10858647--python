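import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def path2():
    """Two nodes, one edge."""
    return nx.path_graph(["a", "b"])


@pytest.fixture
def triangle():
    return nx.complete_graph(["a", "b", "c"])


@pytest.fixture
def path5():
    return nx.path_graph(["n0", "n1", "n2", "n3", "n4"])


@pytest.fixture
def star6():
    """Hub 'h' with five leaves."""
    return nx.star_graph(["h", "l1", "l2", "l3", "l4", "l5"])


@pytest.fixture
def random_graph_factory():
    """Connected random graphs with string labels, deterministic per seed."""

    def make(n: int, p: float = 0.15, seed: int = 0) -> nx.Graph:
        g = nx.fast_gnp_random_graph(n, p, seed=seed)
        # connect stray components so conservation tests see no isolated nodes
        comps = [sorted(c) for c in nx.connected_components(g)]
        for a, b in zip(comps, comps[1:]):
            g.add_edge(a[0], b[0])
        return nx.relabel_nodes(g, {i: f"g{i:04d}" for i in g.nodes})

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
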