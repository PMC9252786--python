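import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `import oracles` work

from drugnet import (
    Drug,
    DrugGeneInteraction,
    Gene,
    GeneInteraction,
    Interactome,
)


def random_gene_graph(rng: np.random.Generator, n_max: int = 30,
                      integer_costs: bool = False, connected: bool = False) -> nx.Graph:
    """Random undirected fuzz graph with cost/weight edge attributes."""
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.1, 0.5))
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    if connected:
        nodes = list(G.nodes)
        for a, b in zip(nodes, nodes[1:]):
            if not G.has_edge(a, b):
                G.add_edge(a, b)
    G = nx.relabel_nodes(G, {i: f"g{i}" for i in G.nodes})
    for u, v in G.edges:
        if integer_costs:
            c = float(rng.integers(1, 4))
            G[u][v]["cost"] = c
            G[u][v]["weight"] = 1.0 / c
        else:
            G[u][v]["cost"] = float(rng.uniform(0.5, 1.0))
            G[u][v]["weight"] = float(rng.uniform(1.0, 2.0))
    return G


def pick_seeds(G: nx.Graph, rng: np.random.Generator, k_min: int = 1, k_max: int = 5) -> set[str]:
    nodes = sorted(G.nodes)
    k = int(rng.integers(k_min, min(k_max, len(nodes)) + 1))
    return set(rng.choice(nodes, size=k, replace=False).tolist())


@pytest.fixture
def small_interactome() -> Interactome:
    """Hand-built 6-gene / 3-drug interactome used across unit tests.

    Gene topology:  A - B - C - D,  B - E,  C - E;  F isolated.
    Drugs: dX -> {A, B} (inhibitor/activator), dY -> {D} (inhibitor),
    dZ -> {E} (other).
    """
    genes = [
        Gene("A", "alpha", {"sarcoma": {"cosmic"}}, {"sarcoma": 0.30}, {"muscle": 10.0}),
        Gene("B", "beta", {"sarcoma": {"cosmic", "ncg6"}}, {"sarcoma": 0.20}, {"muscle": 5.0}),
        Gene("C", "gamma", {}, {"sarcoma": 0.05}, {"muscle": 50.0}),
        Gene("D", "delta", {"lung": {"intogen"}}, {"lung": 0.40}, {"lung": 2.0}),
        Gene("E", "epsilon", {}, {}, {"muscle": 1.0}),
        Gene("F", "phi", {}, {"sarcoma": 0.0}, {}),
    ]
    drugs = [
        Drug("dX", "xantinib", approved=True, atc_l=True, cancerx=True, ctrp=False),
        Drug("dY", "yolimab", approved=False, atc_l=False, cancerx=False, ctrp=True),
        Drug("dZ", "zestat", approved=True, atc_l=False, cancerx=False, ctrp=False),
    ]
    ggi = [
        GeneInteraction("A", "B"),
        GeneInteraction("B", "C"),
        GeneInteraction("C", "D"),
        GeneInteraction("B", "E"),
        GeneInteraction("C", "E"),
    ]
    dgi = [
        DrugGeneInteraction("dX", "A", "inhibitor"),
        DrugGeneInteraction("dX", "B", "activator"),
        DrugGeneInteraction("dY", "D", "inhibitor"),
        DrugGeneInteraction("dZ", "E", "other"),
    ]
    return Interactome(genes=genes, drugs=drugs, ggi=ggi, dgi=dgi)


@pytest.fixture
def path_graph() -> nx.Graph:
    """Unweighted path A - B - C."""
    G = nx.Graph()
    G.add_edge("A", "B")
    G.add_edge("B", "C")
    return G
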