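import math

import networkx as nx
import numpy as np
import pytest


def naive_total_gibbs(network: nx.Graph, concentrations: dict) -> float:
    """Independent double-loop evaluation of G = sum_i c_i ln(c_i / d_i).

    Deliberately naive: scans the raw edge list for every node instead of
    using adjacency structures or vectorization, so it shares no code path
    with the implementation under test.
    """
    edges = list(network.edges)
    total = 0.0
    for node in network.nodes:
        c_i = concentrations.get(node, 0.0)
        if c_i <= 0.0:
            continue  # 0 * ln(0) convention
        denom = c_i
        for a, b in edges:
            if a == node:
                denom += concentrations.get(b, 0.0)
            elif b == node:
                denom += concentrations.get(a, 0.0)
        if denom == c_i:
            continue  # isolated or zero-concentration neighborhood: ln(1)
        total += c_i * math.log(c_i / denom)
    return total


def random_instance(rng: np.random.Generator, max_nodes: int = 12):
    """A random small graph plus a random concentration vector."""
    n = int(rng.integers(1, max_nodes + 1))
    nodes = [f"N{i}" for i in range(n)]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    p = rng.uniform(0.0, 0.8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p:
                graph.add_edge(nodes[i], nodes[j])
    conc = {}
    for node in nodes:
        u = rng.uniform()
        conc[node] = 0.0 if u < 0.15 else float(rng.uniform(0.0, 1.0))
    return graph, conc


@pytest.fixture
def path_network() -> nx.Graph:
    """The hand-worked A–B–C path fixture."""
    return nx.Graph([("A", "B"), ("B", "C")])


@pytest.fixture
def path_concentrations() -> dict:
    return {"A": 1.0, "B": 0.5, "C": 0.25}
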