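import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from herbnet.screening import IngredientRecord


def random_record(rng: np.random.Generator, i: int) -> IngredientRecord:
    """A record with every property drawn to straddle its threshold."""
    return IngredientRecord(
        ingredient_id=f"R{i:04d}",
        name=f"cmpd{i}",
        herbs={"CH"},
        OB=float(rng.uniform(10, 60)),
        GI=str(rng.choice(["High", "high", "Low", "HIGH"])),
        DL=float(rng.uniform(0.05, 0.4)),
        MW=float(rng.uniform(300, 700)),
        Hdon=int(rng.integers(0, 9)),
        Hacc=int(rng.integers(0, 14)),
        iLOGP=float(rng.uniform(2, 8)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_simple_graph(rng: np.random.Generator, max_nodes: int = 7) -> nx.Graph:
    """Random small simple graph, occasionally disconnected."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.9))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
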