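"""Sparse DSN generation from the complete graph.

Two sparsifiers are provided. The first finds the minimum spanning tree of
the complete graph (Prim) and then adds the remaining edges back
probabilistically, ignoring their costs, until a desired edge count is
reached; its output therefore mirrors the complete graph's cost distribution.
The second deletes edges in two passes driven by thresholds t1 < t2: every
edge with cost below t1 is dropped unconditionally, then each surviving edge
with cost below t2 is dropped unless its removal would disconnect the graph.
The unconditional first pass exists to keep the number of (linear-time)
connectivity checks small. Both sparsifiers preserve vertices, prizes and
terminals exactly.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from physteiner.dsn import DrugNetwork, Subnetwork, edge_key
from physteiner.errors import ConnectivityError, ParameterError

__all__ = [
    "SparsifyConfig",
    "check_connected",
    "choose_thresholds",
    "prim_mst",
    "sparsify_mst_augment",
    "sparsify_two_threshold",
]


@dataclass(frozen=True)
class SparsifyConfig:
    """Settings for both sparsifiers.

    desired_edges (De) and add_probability (Pro) drive the MST-augmentation
    sparsifier; t1 < t2 drive the two-threshold deletion sparsifier. The
    threshold defaults are the values used for the reference drug data, where
    the bulk of pairwise costs lies in [0.5, 0.9].
    """

    desired_edges: int = 1500
    add_probability: float = 0.5
    t1: float = 0.9
    t2: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.add_probability <= 1.0:
            raise ParameterError("add_probability must lie in (0, 1]")
        if not self.t1 < self.t2:
            raise ParameterError(f"thresholds must satisfy t1 < t2, got {self.t1} >= {self.t2}")
        if self.desired_edges < 1:
            raise ParameterError("desired_edges must be positive")


def check_connected(network: DrugNetwork) -> bool:
    """True iff every vertex is reachable from every other (linear-time traversal)."""
    g = network.graph
    if g.number_of_nodes() == 0:
        return False
    return nx.is_connected(g)


def choose_thresholds(
    network: DrugNetwork, quantiles: tuple[float, float] = (0.95, 0.99)
) -> tuple[float, float]:
    """Pick (t1, t2) for the two-threshold sparsifier from the data.

    t1 must be small enough that deleting every edge below it leaves the
    graph connected. The exact largest safe value is the bottleneck of the
    *maximum* spanning tree (the graph of edges >= t stays connected iff t
    does not exceed the cheapest max-spanning-tree edge), so t1 is the
    requested cost quantile capped at that bottleneck. t2 is the second
    quantile, nudged above t1 if the distribution is so tight that the two
    coincide.
    """
    q1, q2 = quantiles
    if not 0.0 <= q1 <= q2 <= 1.0:
        raise ParameterError("quantiles must satisfy 0 <= q1 <= q2 <= 1")
    if not check_connected(network):
        raise ConnectivityError("threshold selection requires a connected graph")
    costs = np.array(list(network.costs.values()))
    bottleneck = min(
        d["cost"]
        for _, _, d in nx.maximum_spanning_edges(
            network.graph, weight="cost", data=True
        )
    )
    t1 = min(float(np.quantile(costs, q1)), float(bottleneck))
    t2 = max(float(np.quantile(costs, q2)), float(np.nextafter(t1, np.inf)))
    return t1, t2


def prim_mst(network: DrugNetwork) -> Subnetwork:
    """Minimum spanning tree by Prim's algorithm.

    Deterministic: growth starts at the lexicographically smallest vertex and
    ties are broken by (cost, sorted vertex-id pair).
    """
    g = network.graph
    if not check_connected(network):
        raise ConnectivityError("cannot build an MST of a disconnected graph")
    nodes = sorted(g.nodes)
    start = nodes[0]
    in_tree = {start}
    edges: list[tuple[str, str]] = []
    heap: list[tuple[float, str, str, str]] = []

    def push_edges(u: str) -> None:
        for v in g.neighbors(u):
            if v not in in_tree:
                a, b = edge_key(u, v)
                heapq.heappush(heap, (g.edges[u, v]["cost"], a, b, v))

    push_edges(start)
    while len(in_tree) < len(nodes):
        cost, a, b, v = heapq.heappop(heap)
        if v in in_tree:
            continue
        in_tree.add(v)
        edges.append((a, b))
        push_edges(v)
    return Subnetwork(vertices=frozenset(nodes), edges=frozenset(edges), parent=network)


def sparsify_mst_augment(network: DrugNetwork, config: SparsifyConfig) -> DrugNetwork:
    """Keep the MST and add non-MST edges probabilistically up to ``desired_edges``.

    Non-MST edges are scanned in a seeded random order; each is added with
    probability ``add_probability``, re-scanning the remaining candidates
    until exactly ``desired_edges`` edges are present. Edge costs play no
    role in the selection.
    """
    n = network.n_vertices
    de = config.desired_edges
    if de < n - 1:
        raise ParameterError(f"desired_edges={de} is below |V|-1={n - 1}")
    if de > network.n_edges:
        raise ParameterError(
            f"desired_edges={de} exceeds the {network.n_edges} edges available"
        )
    mst = prim_mst(network)
    chosen = set(mst.edges)
    rng = np.random.default_rng(config.seed)
    candidates = sorted(set(network.costs) - chosen)
    perm = rng.permutation(len(candidates))
    scan = [candidates[k] for k in perm]
    while len(chosen) < de:
        remaining = [e for e in scan if e not in chosen]
        accepted = rng.random(len(remaining)) < config.add_probability
        for e, ok in zip(remaining, accepted):
            if ok:
                chosen.add(e)
                if len(chosen) == de:
                    break
    return network.with_edges(chosen)


def sparsify_two_threshold(network: DrugNetwork, config: SparsifyConfig) -> DrugNetwork:
    """Two-pass threshold deletion.

    Pass 1 removes every edge with cost < t1; if that disconnects the graph
    the call fails (t1 was too large for this cost distribution). Pass 2
    scans the survivors with cost < t2 in ascending (cost, vertex-id pair)
    order and removes each unless removal would disconnect the graph, so
    every surviving sub-t2 edge is a bridge of the output.
    """
    if not check_connected(network):
        raise ConnectivityError("two-threshold sparsifier requires a connected input")
    t1, t2 = config.t1, config.t2
    g = network.graph.copy()
    g.remove_edges_from(
        [(u, v) for u, v, d in g.edges(data=True) if d["cost"] < t1]
    )
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ConnectivityError(
            f"graph disconnected after deleting all edges with cost < t1={t1}; "
            "choose a smaller t1"
        )
    scan = sorted(
        (
            (d["cost"], *edge_key(u, v))
            for u, v, d in g.edges(data=True)
            if d["cost"] < t2
        ),
    )
    for cost, u, v in scan:
        g.remove_edge(u, v)
        # a non-bridge removal leaves u and v connected
        if not nx.has_path(g, u, v):
            g.add_edge(u, v, cost=cost)
    return network.with_edges(edge_key(u, v) for u, v in g.edges)
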