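import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the md5 test oracle

from wgevia import Microcircuit, MicrocircuitDataset, UnweightedGraph


@pytest.fixture
def path_graph():
    """Path 1-2-3 on k=3."""
    return UnweightedGraph.from_edges(3, [(1, 2), (2, 3)])


@pytest.fixture
def single_edge_k5():
    return UnweightedGraph.from_edges(5, [(1, 2)])


def random_graph(rng: np.random.Generator, k: int, p: float = 0.4) -> UnweightedGraph:
    edges = [
        (i, j)
        for i in range(1, k + 1)
        for j in range(i + 1, k + 1)
        if rng.random() < p
    ]
    return UnweightedGraph.from_edges(k, edges)


def random_weighted_dataset(
    rng: np.random.Generator, n: int, k: int, p: float = 0.5
) -> MicrocircuitDataset:
    members = []
    for _ in range(n):
        g = random_graph(rng, k, p)
        weights = {e: float(rng.random()) for e in g.edges}
        members.append(Microcircuit(g, weights))
    return MicrocircuitDataset(members, common_vertex_count=k)
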