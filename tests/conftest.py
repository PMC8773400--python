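import numpy as np
import pandas as pd
import pytest

from cardtrace import GeneratorConfig
from cardtrace.printed_tables import (
    CARD_N_NODES,
    DAILY_RECIPROCITY,
    REPORT_N_NODES,
    reconstruct_daily_counts,
)
from cardtrace.reciprocity import DailyDirectedNetwork, network_from_census

network_with_census = network_from_census


@pytest.fixture(scope="session")
def reconstructed_counts() -> pd.DataFrame:
    return reconstruct_daily_counts()


def random_network(rng: np.random.Generator, n_nodes: int, n_edges: int, day=1):
    """Random directed network with exactly n_edges distinct edges."""
    nodes = list(range(n_nodes))
    edges = set()
    while len(edges) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            edges.add((int(i), int(j)))
    return DailyDirectedNetwork(day, frozenset(nodes), frozenset(edges))


@pytest.fixture(scope="session")
def published_networks():
    """Synthetic networks realising each published daily dyad census."""
    nets = {}
    for row in DAILY_RECIPROCITY:
        succ = round(row.r * row.n_edges)
        assert succ % 2 == 0
        n_nodes = CARD_N_NODES if row.dataset == "card" else REPORT_N_NODES
        nets[(row.dataset, row.day)] = network_with_census(
            n_nodes, succ // 2, row.n_edges - succ, day=row.day
        )
    return nets


@pytest.fixture
def tiny_config() -> GeneratorConfig:
    return GeneratorConfig(n_participants=40, n_days=3, n_interviewed=10,
                           wear_prob_by_day=[0.9, 0.8, 0.7], seed=11)
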