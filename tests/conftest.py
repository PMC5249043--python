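"""Shared fixtures: tiny planted datasets and random small PCST instances."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from physteiner.datagen import generate_feature_table
from physteiner.dsn import DrugNetwork, build_complete_dsn


def make_network(prizes, costs, terminals) -> DrugNetwork:
    """Build a DrugNetwork from plain dicts (tests' shorthand)."""
    return DrugNetwork.from_maps(prizes=prizes, costs=costs, terminals=terminals)


def triangle_network() -> DrugNetwork:
    """Three vertices where the 2-edge detour through the prized vertex 'c'
    beats the direct terminal-terminal edge both in the prize-collecting
    objective (0.4 - 0.5 < 1.0) and in prize-discounted net-cost path length
    (2 x 0.95 < 2.0), so flow dynamics and exhaustive search agree on it:
    costs ab=1.0, ac=bc=0.2, prize(c)=0.5, terminals {a, b}."""
    return make_network(
        prizes={"a": 0.0, "b": 0.0, "c": 0.5},
        costs={("a", "b"): 1.0, ("a", "c"): 0.2, ("b", "c"): 0.2},
        terminals={"a", "b"},
    )


def random_instance(seed: int, max_vertices: int = 8) -> DrugNetwork:
    """Random small connected PCST instance with 2-4 terminals."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_vertices + 1))
    while True:
        g = nx.gnp_random_graph(n, 0.55, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() >= n - 1:
            break
    names = [f"v{i}" for i in range(n)]
    prizes = {names[i]: float(rng.uniform(0.0, 0.8)) for i in range(n)}
    costs = {
        (names[min(u, v)], names[max(u, v)]): float(rng.uniform(0.2, 1.0))
        for u, v in g.edges
    }
    n_term = int(rng.integers(2, min(4, n) + 1))
    terminals = set(rng.choice(names, size=n_term, replace=False))
    return make_network(prizes, costs, terminals)


@pytest.fixture(scope="session")
def tiny_data():
    """30 drugs, two planted classes of 5, modest feature space."""
    return generate_feature_table(
        30,
        block_sizes=[200, 200],
        classes=[("C01", 5), ("C02", 5)],
        within_class_feature_rate=0.9,
        background_rate=(0.1, 0.4),
        shared_core_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dsn(tiny_data):
    table, membership = tiny_data
    return build_complete_dsn(table, "C01", membership)


@pytest.fixture
def triangle():
    return triangle_network()
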