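import networkx as nx
import pytest

from netpharm.synthetic import SimulationConfig


@pytest.fixture
def small_config():
    """Small, fast synthetic scenario used by several suites."""
    return SimulationConfig(
        seed=42,
        n_nodes=150,
        edges_per_new_node=3,
        n_genes=300,
        n_tumor=8,
        n_normal=8,
        n_de=20,
        n_terms=20,
        term_size_range=(5, 30),
    )


def random_connected_graph(rng, n_max=60, n_min=4, p_extra=0.05):
    """Random connected simple graph: spanning tree plus extra edges."""
    n = int(rng.integers(n_min, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for v in range(1, n):
        g.add_edge(v, int(rng.integers(0, v)))
    for u in range(n):
        for v in range(u + 1, n):
            if not g.has_edge(u, v) and rng.random() < p_extra:
                g.add_edge(u, v)
    return g
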