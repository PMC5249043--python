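"""Multi-terminal Goemans-Williamson moat growing with strong pruning.

The classic GW prize-collecting Steiner heuristic is rooted at a single
vertex. For multi-terminal instances one terminal is chosen uniformly at
random as the root and every other terminal receives a big prize
M > sum of all edge costs, which guarantees that all terminals end up in the
root component (a terminal's surplus can never be exhausted before the edge
deficits on some root path close).

Growth proceeds on components. Each component starts as a single vertex with
surplus equal to its (possibly boosted) prize; the root component is always
inactive and a component is active while its surplus is positive. Each edge
starts with a deficit equal to its cost and is active while its endpoints
lie in different components. Growing by dt reduces every active component's
surplus by dt and every active edge's deficit by dt per adjacent active
component (2 dt when both sides are active). An edge whose deficit reaches 0
merges its two components (surpluses add); a component whose surplus reaches
0 is deactivated. Growth ends when no active component remains.

The merge edges inside the final root component form a tree, which is then
strong-pruned: a bottom-up dynamic program computes each subtree's net worth
NW(v) = prize(v) + sum over children u of max(0, NW(u) - cost(v, u)) and
deletes every subtree that cannot pay for its connecting edge. The pruned
tree is the identified subnetwork (no trailing MST step).

The growth is implemented event-driven: dt is always the exact distance to
the next deficit-zero or surplus-zero event, which is the limit of the
discrete fixed-step iteration as the step size goes to 0 and removes the
otherwise arbitrary step constant. A fixed-step reference mode is kept for
equivalence checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from physteiner.dsn import DrugNetwork, Subnetwork, edge_key
from physteiner.errors import StructureError

__all__ = [
    "RootedInstance",
    "GrowthResult",
    "make_rooted_instance",
    "gw_grow",
    "strong_prune",
    "gw_identify",
]

Edge = tuple[str, str]

_EPS = 1e-12


@dataclass(frozen=True)
class RootedInstance:
    """A network with a chosen root terminal and boosted non-root terminal prizes."""

    network: DrugNetwork
    root: str
    prizes: Mapping[str, float]
    big_prize: float

    def __post_init__(self) -> None:
        if self.root not in self.network.terminals:
            raise StructureError("root must be a terminal")


@dataclass
class GrowthResult:
    """Outcome of the moat growth: the root component's tree and the merge order."""

    tree: Subnetwork
    merge_sequence: list[Edge] = field(default_factory=list)


def make_rooted_instance(network: DrugNetwork, seed: int) -> RootedInstance:
    """Pick a uniform random root terminal and boost the other terminals.

    The boost is M = (sum of all edge costs) + 1, strictly exceeding the
    total edge cost as the inclusion guarantee requires.
    """
    rng = np.random.default_rng(seed)
    terminals = sorted(network.terminals)
    root = terminals[int(rng.integers(len(terminals)))]
    m = sum(network.costs.values()) + 1.0
    prizes = network.prizes
    boosted = {
        v: (m if (v in network.terminals and v != root) else p)
        for v, p in prizes.items()
    }
    return RootedInstance(network=network, root=root, prizes=boosted, big_prize=m)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        self.parent[rb] = ra
        return ra


def gw_grow(instance: RootedInstance, delta: float | None = None) -> GrowthResult:
    """Run the moat growth and return the root component's merge tree.

    With ``delta=None`` (default) the growth is event-driven: each round
    advances time exactly to the next event. With a positive ``delta`` the
    discrete fixed-step iteration is emulated instead: time advances in whole
    multiples of ``delta`` and events trigger once their quantity is <= 0,
    exactly as in a step-by-step loop. Simultaneous events are resolved by
    deactivating exhausted components first and then merging closed edges in
    ascending vertex-id-pair order.
    """
    net = instance.network
    g = net.graph
    uf = _UnionFind(g.nodes)
    surplus = {v: float(instance.prizes[v]) for v in g.nodes}
    active = {v: surplus[v] > 0.0 for v in g.nodes}
    active[uf.find(instance.root)] = False  # the root component is always inactive
    deficit = {edge_key(u, v): float(d["cost"]) for u, v, d in g.edges(data=True)}
    merges: list[Edge] = []

    def edge_sides(e: Edge) -> int:
        ru, rv = uf.find(e[0]), uf.find(e[1])
        if ru == rv:
            return -1  # inactive: internal edge
        return int(active[ru]) + int(active[rv])

    while True:
        roots = {uf.find(v) for v in g.nodes}
        active_roots = [r for r in roots if active[r]]
        if not active_roots:
            break
        # time to the next event
        t_min = math.inf
        for r in active_roots:
            t_min = min(t_min, surplus[r])
        live_edges: list[tuple[Edge, int]] = []
        for e, d in deficit.items():
            sides = edge_sides(e)
            if sides > 0:
                live_edges.append((e, sides))
                t_min = min(t_min, d / sides)
        if not math.isfinite(t_min):  # pragma: no cover - defensive
            break
        if delta is None:
            dt = max(t_min, 0.0)
        else:
            steps = max(1, math.ceil(t_min / delta - 1e-9))
            dt = steps * delta
        for r in active_roots:
            surplus[r] -= dt
        for e, sides in live_edges:
            deficit[e] -= sides * dt
        # deactivations first, then merges, for deterministic tie handling
        for r in active_roots:
            if surplus[r] <= _EPS:
                active[r] = False
        for e, _ in sorted(live_edges):
            if deficit.get(e, 1.0) <= _EPS:
                ru, rv = uf.find(e[0]), uf.find(e[1])
                if ru == rv:
                    continue
                merged_surplus = surplus[ru] + surplus[rv]
                is_root_comp = (
                    uf.find(instance.root) in (ru, rv)
                )
                r_new = uf.union(ru, rv)
                surplus[r_new] = merged_surplus
                active[r_new] = (merged_surplus > _EPS) and not is_root_comp
                merges.append(e)
                del deficit[e]

    root_comp = uf.find(instance.root)
    vertices = frozenset(v for v in g.nodes if uf.find(v) == root_comp)
    tree_edges = frozenset(e for e in merges if uf.find(e[0]) == root_comp)
    tree = Subnetwork(vertices=vertices, edges=tree_edges, parent=net)
    return GrowthResult(tree=tree, merge_sequence=merges)


def strong_prune(
    tree: Subnetwork,
    root: str,
    prizes: Mapping[str, float],
    costs: Mapping[Edge, float] | None = None,
) -> Subnetwork:
    """Strong-prune a rooted tree.

    Bottom-up, the net worth of vertex v is
    ``NW(v) = prize(v) + sum_children max(0, NW(u) - cost(v, u))`` and a
    child subtree is deleted when ``NW(u) - cost(v, u) <= 0``. The root is
    always retained. Subtrees containing a big-prize terminal can never be
    deleted because their net worth exceeds the total edge cost.
    """
    if root not in tree.vertices:
        raise StructureError("root must be in the tree")
    if not tree.is_tree():
        raise StructureError("strong pruning requires a tree input")
    if costs is None:
        costs = {e: tree.parent.cost(*e) for e in tree.edges}
    g = nx.Graph()
    g.add_nodes_from(tree.vertices)
    g.add_edges_from(tree.edges)
    order = list(nx.dfs_postorder_nodes(g, root))
    parent = nx.dfs_predecessors(g, root)
    nw: dict[str, float] = {}
    kept_children: dict[str, list[str]] = {v: [] for v in tree.vertices}
    for v in order:
        total = float(prizes[v])
        for u in g.neighbors(v):
            if parent.get(u) == v:
                margin = nw[u] - costs[edge_key(u, v)]
                if margin > 0.0:
                    total += margin
                    kept_children[v].append(u)
        nw[v] = total
    vertices: set[str] = set()
    edges: set[Edge] = set()
    stack = [root]
    while stack:
        v = stack.pop()
        vertices.add(v)
        for u in kept_children[v]:
            edges.add(edge_key(u, v))
            stack.append(u)
    return Subnetwork(vertices=frozenset(vertices), edges=frozenset(edges), parent=tree.parent)


def gw_identify(network: DrugNetwork, seed: int) -> Subnetwork:
    """Root, grow, strong-prune: the full multi-terminal GW heuristic.

    The strong-pruned tree itself is the identified subnetwork; no MST
    post-processing is applied. The result is a tree containing every
    terminal.
    """
    if not nx.is_connected(network.graph):
        raise StructureError("GW requires a connected network")
    instance = make_rooted_instance(network, seed)
    growth = gw_grow(instance)
    pruned = strong_prune(growth.tree, instance.root, instance.prizes)
    missing = network.terminals - pruned.vertices
    if missing:  # pragma: no cover - guarded by the big-prize construction
        raise StructureError(f"terminals missing from GW subnetwork: {sorted(missing)[:3]}")
    return pruned
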