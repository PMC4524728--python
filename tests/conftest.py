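import networkx as nx
import numpy as np
import pytest


def random_battery(n_graphs: int = 60, max_nodes: int = 12, seed: int = 0):
    """Seeded battery of small random graphs (Erdős–Rényi at varied density)."""
    rng = np.random.default_rng(seed)
    graphs = []
    while len(graphs) < n_graphs:
        n = int(rng.integers(4, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.75))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(1_000_000)))
        G = nx.relabel_nodes(G, lambda i: f"v{i:02d}")
        if G.number_of_edges() >= 2:
            graphs.append(G)
    return graphs


@pytest.fixture(scope="session")
def battery():
    return random_battery()


@pytest.fixture(scope="session")
def barbell():
    """Two K4s joined by a 3-node path (11 nodes)."""
    G = nx.Graph()
    for base in (0, 7):
        for i in range(4):
            for j in range(i + 1, 4):
                G.add_edge(base + i, base + j)
    for u, v in [(3, 4), (4, 5), (5, 6), (6, 7)]:
        G.add_edge(u, v)
    return nx.relabel_nodes(G, lambda i: f"b{i:02d}")


@pytest.fixture(scope="session")
def k5():
    return nx.relabel_nodes(nx.complete_graph(5), str)


@pytest.fixture(scope="session")
def star4():
    return nx.relabel_nodes(nx.star_graph(4), str)


@pytest.fixture(scope="session")
def path3():
    return nx.relabel_nodes(nx.path_graph(3), str)
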