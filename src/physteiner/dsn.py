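"""Drug similarity network (DSN) assembly.

A DSN is a complete undirected graph over drugs. The cost of edge (i, j) is
the Jaccard dissimilarity of the two drugs' binary feature vectors,

    c_ij = 1 - |v_i AND v_j| / |v_i OR v_j|,

and the prize of vertex i measures its mean similarity to the terminal set T
(the drugs of one therapeutic subclass),

    p_i = ( sum_{j in T, j != i} 1 / (1 + c_ij) ) / |T|.

Small costs therefore connect similar drugs and large prizes mark drugs close
to the terminal subclass, so a minimum net-cost (prize-collecting Steiner)
subnetwork gathers drugs that resemble the terminals. Prizes are computed on
the complete graph's pairwise costs and frozen before any sparsification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

from physteiner.datagen import ClassMembership, FeatureTable
from physteiner.errors import (
    InputError,
    ParameterError,
    StructureError,
    UndefinedSimilarityError,
)

__all__ = [
    "DrugNetwork",
    "Subnetwork",
    "jaccard_cost",
    "jaccard_cost_matrix",
    "vertex_prize",
    "build_complete_dsn",
    "edge_key",
    "COST_FLOOR",
]

#: Floor applied to edge costs at assembly: the prize-collecting Steiner
#: formulation requires strictly positive costs, but identical feature
#: vectors yield a Jaccard cost of exactly 0.
COST_FLOOR = 1e-9

Edge = tuple[str, str]


def edge_key(u: str, v: str) -> Edge:
    """Canonical (sorted) representation of an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class DrugNetwork:
    """An undirected weighted graph with vertex prizes and a terminal set.

    Vertices carry non-negative prizes, edges carry strictly positive costs,
    and ``terminals`` is the subset of vertices every feasible subnetwork must
    span. Vertex order is lexicographic by id everywhere, for determinism.
    """

    graph: nx.Graph
    terminals: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terminals", frozenset(self.terminals))
        missing = self.terminals - set(self.graph.nodes)
        if missing:
            raise StructureError(f"terminals not in vertex set: {sorted(missing)[:5]}")
        if len(self.terminals) < 2:
            raise StructureError("a DSN needs at least 2 terminals")
        for u, v, data in self.graph.edges(data=True):
            if data.get("cost", 0.0) <= 0.0:
                raise StructureError(f"edge ({u}, {v}) has non-positive cost")
        for v, data in self.graph.nodes(data=True):
            if data.get("prize", 0.0) < 0.0:
                raise StructureError(f"vertex {v} has negative prize")

    @classmethod
    def from_maps(
        cls,
        prizes: Mapping[str, float],
        costs: Mapping[Edge, float],
        terminals: Iterable[str],
    ) -> "DrugNetwork":
        g = nx.Graph()
        for v in sorted(prizes):
            g.add_node(v, prize=float(prizes[v]))
        for (u, v), c in costs.items():
            g.add_edge(u, v, cost=float(c))
        return cls(graph=g, terminals=frozenset(terminals))

    @property
    def vertex_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def prizes(self) -> dict[str, float]:
        return {v: float(d.get("prize", 0.0)) for v, d in self.graph.nodes(data=True)}

    @property
    def costs(self) -> dict[Edge, float]:
        return {
            edge_key(u, v): float(d["cost"]) for u, v, d in self.graph.edges(data=True)
        }

    def cost(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["cost"])

    def prize(self, v: str) -> float:
        return float(self.graph.nodes[v].get("prize", 0.0))

    def with_edges(self, edges: Iterable[Edge]) -> "DrugNetwork":
        """Same vertices/prizes/terminals, edge set restricted to ``edges``."""
        g = nx.Graph()
        for v in sorted(self.graph.nodes):
            g.add_node(v, prize=self.prize(v))
        for u, v in edges:
            g.add_edge(u, v, cost=self.cost(u, v))
        return DrugNetwork(graph=g, terminals=self.terminals)


@dataclass(frozen=True)
class Subnetwork:
    """A subgraph of a parent network; the solvers return terminal-spanning trees."""

    vertices: frozenset[str]
    edges: frozenset[Edge]
    parent: DrugNetwork

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", frozenset(self.vertices))
        object.__setattr__(
            self, "edges", frozenset(edge_key(u, v) for u, v in self.edges)
        )
        parent_nodes = set(self.parent.graph.nodes)
        if not self.vertices <= parent_nodes:
            raise StructureError("subnetwork vertices not in parent network")
        for u, v in self.edges:
            if not self.parent.graph.has_edge(u, v):
                raise StructureError(f"subnetwork edge ({u}, {v}) missing from parent")
            if u not in self.vertices or v not in self.vertices:
                raise StructureError(f"edge ({u}, {v}) has endpoint outside vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def as_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for u, v in self.edges:
            g.add_edge(u, v, cost=self.parent.cost(u, v))
        return g

    def is_tree(self) -> bool:
        if not self.vertices:
            return False
        return len(self.edges) == len(self.vertices) - 1 and nx.is_connected(
            self.as_graph()
        )

    def contains_terminals(self) -> bool:
        return self.parent.terminals <= self.vertices

    def total_cost(self) -> float:
        return sum(self.parent.cost(u, v) for u, v in self.edges)

    def total_prize(self) -> float:
        return sum(self.parent.prize(v) for v in self.vertices)


def jaccard_cost(v_i: np.ndarray, v_j: np.ndarray) -> float:
    """Jaccard dissimilarity between two binary feature vectors.

    Raises
    ------
    UndefinedSimilarityError
        If both vectors are all-zero (the union is empty). Callers decide how
        to handle featureless drugs; network assembly maps such pairs to the
        maximal cost 1.
    """
    a = np.asarray(v_i, dtype=bool)
    b = np.asarray(v_j, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ParameterError("feature vectors must be 1-D and of equal length >= 1")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise UndefinedSimilarityError("both feature vectors are all-zero")
    inter = int(np.count_nonzero(a & b))
    return 1.0 - inter / union


def jaccard_cost_matrix(matrix: np.ndarray) -> np.ndarray:
    """All-pairs Jaccard costs of the rows of a binary matrix.

    Pairs where both rows are all-zero get cost 1.0 (maximally dissimilar)
    with a warning; the diagonal is 0.
    """
    m = np.asarray(matrix, dtype=np.float64)
    inter = m @ m.T
    row_sums = m.sum(axis=1)
    union = row_sums[:, None] + row_sums[None, :] - inter
    empty = union == 0
    if empty.any():
        n_empty = int(np.count_nonzero(row_sums == 0))
        warnings.warn(
            f"{n_empty} drug(s) have all-zero feature vectors; "
            "their mutual costs are set to 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = 1.0 - np.divide(inter, union, out=np.zeros_like(inter), where=~empty)
    cost[empty] = 1.0
    np.fill_diagonal(cost, 0.0)
    return cost


def vertex_prize(
    i: str,
    terminals: Iterable[str],
    cost_lookup: Callable[[str, str], float],
) -> float:
    """Mean similarity of vertex ``i`` to the terminal set.

    The sum runs over terminals j != i but is divided by |T| in every case,
    so a terminal's own prize uses |T| - 1 summands over the same denominator.
    """
    terms = sorted(set(terminals))
    if not terms:
        raise ParameterError("terminal set must be non-empty")
    total = sum(1.0 / (1.0 + cost_lookup(i, j)) for j in terms if j != i)
    return total / len(terms)


def build_complete_dsn(
    table: FeatureTable,
    terminal_subclass: str,
    membership: ClassMembership,
) -> DrugNetwork:
    """Assemble the complete DSN for one terminal subclass.

    Every drug pair gets a Jaccard-cost edge (clamped below by
    :data:`COST_FLOOR`); every vertex gets its prize with T = the subclass
    members. The cost map is identical across terminal choices on the same
    table; only prizes and terminals differ.
    """
    terminals = membership.members(terminal_subclass)
    missing = terminals - set(table.drug_ids)
    if missing:
        raise InputError(
            f"subclass {terminal_subclass!r} members missing from table: "
            f"{sorted(missing)[:5]}"
        )
    if len(terminals) < 2:
        raise InputError(f"subclass {terminal_subclass!r} has fewer than 2 members")

    order = np.argsort(np.array(table.drug_ids))
    ids = [table.drug_ids[k] for k in order]
    cost = jaccard_cost_matrix(table.matrix[order])

    # Prizes from the raw pairwise costs (Eq-style mean similarity to T).
    t_idx = [ids.index(t) for t in sorted(terminals)]
    sim = 1.0 / (1.0 + cost)
    n_t = len(t_idx)
    prize_vec = np.zeros(len(ids))
    for k in t_idx:
        prize_vec += sim[:, k]
    # remove self-similarity terms for the terminals themselves
    for k in t_idx:
        prize_vec[k] -= sim[k, k]
    prize_vec /= n_t

    g = nx.Graph()
    for k, v in enumerate(ids):
        g.add_node(v, prize=float(prize_vec[k]))
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    clamped = np.maximum(cost[iu, ju], COST_FLOOR)
    g.add_edges_from(
        (ids[a], ids[b], {"cost": float(c)}) for a, b, c in zip(iu, ju, clamped)
    )
    return DrugNetwork(graph=g, terminals=terminals)
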