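import numpy as np
import pandas as pd
import pytest

from survmod.network import WeightedNetwork, build_weighted_network
from survmod.simulate import SimulationConfig, generate_bundle


def toy_network(node_weights: dict, edge_weights: dict) -> WeightedNetwork:
    """Build a WeightedNetwork directly from weight dictionaries.

    ``edge_weights`` maps (gene_a, gene_b) pairs to w_e.
    """
    nodes = pd.Series(node_weights, dtype=float)
    rows = [
        {"gene_a": a, "gene_b": b, "weight": w, "r_longer": 0.0, "r_shorter": 0.0}
        for (a, b), w in edge_weights.items()
    ]
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "r_longer", "r_shorter"])
    return WeightedNetwork(node_weights=nodes, edges=edges)


def random_toy_network(n_nodes: int, edge_prob: float, rng: np.random.Generator) -> WeightedNetwork:
    """Random graph with N(0,1) node weights and |N(0,1)| edge weights."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    node_w = dict(zip(names, rng.standard_normal(n_nodes)))
    edge_w = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edge_w[(names[i], names[j])] = abs(rng.standard_normal())
    return toy_network(node_w, edge_w)


@pytest.fixture(scope="session")
def planted_bundle():
    """Default study conditions with the planted 12-gene module."""
    return generate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def null_bundle():
    """No survival effect, no differential co-expression."""
    return generate_bundle(SimulationConfig(node_effect=0.0, edge_effect=0.0, seed=2))


@pytest.fixture(scope="session")
def planted_network(planted_bundle):
    return build_weighted_network(planted_bundle.cohorts["training"], planted_bundle.network)


@pytest.fixture(scope="session")
def null_network(null_bundle):
    return build_weighted_network(null_bundle.cohorts["training"], null_bundle.network)
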