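import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from vdsignalflow import CountMatrix, SimConfig, simulate_all  # noqa: E402


@pytest.fixture
def small_counts() -> CountMatrix:
    """Toy 3-gene x 4-sample count matrix with two conditions, two batches."""
    counts = pd.DataFrame(
        [[10, 20, 12, 24], [30, 60, 28, 56], [5, 10, 6, 12]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2", "t1", "t2"])
    meta = pd.DataFrame(
        {"condition": ["control", "control", "treatment", "treatment"],
         "batch": ["A", "B", "A", "B"]},
        index=["c1", "c2", "t1", "t2"])
    return CountMatrix(counts=counts, meta=meta)


@pytest.fixture(scope="session")
def default_bundle() -> dict:
    """One full simulation at the default study conditions (seed 11)."""
    return simulate_all(SimConfig(seed=11))


def random_digraph(rng: np.random.Generator, n_nodes: int,
                   edge_prob: float = 0.3):
    """Erdos-Renyi style random directed graph with string node names."""
    import networkx as nx
    g = nx.DiGraph()
    names = [f"n{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_prob:
                g.add_edge(names[i], names[j])
    return g


def brute_force_shortest_paths(g, source, target):
    """Oracle: enumerate ALL simple paths by DFS, keep the minimal length.

    Independent of the BFS/DAG implementation under test.
    """
    import networkx as nx
    if source == target:
        return [(source,)]
    try:
        all_paths = [tuple(p) for p in nx.all_simple_paths(g, source, target)]
    except nx.NodeNotFound:
        return []
    if not all_paths:
        return []
    d = min(len(p) for p in all_paths)
    return sorted(p for p in all_paths if len(p) == d)
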