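import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from labne.embedding import labne_embed
from labne.ps_model import PSParams, grow_ps_network

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_linkpred_graph():
    """The 5-edge hand-evaluation graph: x-a, x-b, y-a, y-b, a-b."""
    G = nx.Graph()
    G.add_edges_from([("x", "a"), ("x", "b"), ("y", "a"), ("y", "b"), ("a", "b")])
    return G


@pytest.fixture(scope="session")
def small_ps_net():
    """One modest cold PS network with ground truth, for reuse."""
    params = PSParams(N=300, m=4, gamma=2.5, T=0.0, seed=7)
    graph, coords = grow_ps_network(params)
    return params, graph, coords


@pytest.fixture(scope="session")
def dense_cold_replicates():
    """Ten dense cold PS networks (N=500, 2m=10, gamma=2.25, T=0) with
    their LaBNE embeddings -- the recovery benchmark's study condition,
    shared across the distance-recovery and evolution analyses."""
    out = []
    for seed in range(1, 11):
        params = PSParams(N=500, m=5, gamma=2.25, T=0.0, seed=seed)
        graph, coords = grow_ps_network(params)
        out.append((params, graph, coords, labne_embed(graph, gamma=2.25)))
    return out


def degrees_of(graph):
    return np.array([d for _, d in graph.degree()])
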