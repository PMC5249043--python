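"""Subnetwork scoring, exact small-instance solving, and candidate ranking.

A subnetwork is judged against a drug *superclass* (e.g. a whole therapeutic
class whose subclasses supplied the terminals) with a Rand Index over the
non-terminal vertices:

    RI = (I_c + N_nc) / (|V| - |T|) * 100,

where I_c counts non-terminal subnetwork members inside the superclass (true
positives) and N_nc counts drugs neither in the subnetwork nor in the
superclass (true negatives). The prize-collecting objective of a subnetwork
is sum of its edge costs minus sum of its vertex prizes.

Repositioning candidates are drugs outside the superclass that recur across
the selected subnetworks; their occurrence frequency is the ranking signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from physteiner.dsn import DrugNetwork, Subnetwork, edge_key
from physteiner.errors import InputError, ParameterError, StructureError
from physteiner.sparsify import prim_mst

__all__ = [
    "EvaluationResult",
    "CandidateRanking",
    "rand_index",
    "rand_index_from_counts",
    "pcst_objective",
    "brute_force_pcst",
    "select_best",
    "candidate_frequencies",
    "network_summary_stats",
    "SummaryStats",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Rand Index decomposition and objective for one subnetwork."""

    rand_index: float  # percentage in [0, 100]
    i_c: int
    n_nc: int
    objective: float
    n_vertices: int
    n_edges: int


@dataclass(frozen=True)
class CandidateRanking:
    """Occurrence frequencies of out-of-superclass drugs across selected subnetworks."""

    frequencies: dict[str, int]
    candidates: tuple[str, ...]
    threshold: int


def rand_index_from_counts(
    n_vertices: int,
    superclass_size: int,
    n_terminals: int,
    subnet_size: int,
    i_c: int,
) -> float:
    """Rand Index (percent) from summary counts alone.

    Assumes terminals belong to the superclass and to the subnetwork, so the
    number of true negatives is
    ``(n_vertices - subnet_size) - (superclass_size - n_terminals - i_c)``.
    """
    if i_c > subnet_size - n_terminals:
        raise ParameterError("i_c cannot exceed the non-terminal subnetwork size")
    n_nc = (n_vertices - subnet_size) - (superclass_size - n_terminals - i_c)
    if n_nc < 0:
        raise ParameterError("inconsistent counts: negative true-negative count")
    return (i_c + n_nc) / (n_vertices - n_terminals) * 100.0


def rand_index(
    subnetwork: Subnetwork, network: DrugNetwork, superclass: Iterable[str]
) -> EvaluationResult:
    """Score a terminal-spanning subnetwork against a superclass of drugs."""
    superclass = frozenset(superclass)
    terminals = network.terminals
    if not terminals <= superclass:
        raise InputError("every terminal must belong to the superclass")
    if not terminals <= subnetwork.vertices:
        raise InputError("subnetwork does not contain all terminals")
    all_vertices = set(network.graph.nodes)
    non_terminal_members = subnetwork.vertices - terminals
    i_c = len(non_terminal_members & superclass)
    n_nc = len((all_vertices - subnetwork.vertices) - superclass)
    ri = (i_c + n_nc) / (len(all_vertices) - len(terminals)) * 100.0
    return EvaluationResult(
        rand_index=ri,
        i_c=i_c,
        n_nc=n_nc,
        objective=pcst_objective(subnetwork, network),
        n_vertices=subnetwork.n_vertices,
        n_edges=subnetwork.n_edges,
    )


def pcst_objective(subnetwork: Subnetwork, network: DrugNetwork) -> float:
    """Prize-collecting objective: sum of edge costs minus sum of vertex prizes."""
    for u, v in subnetwork.edges:
        if not network.graph.has_edge(u, v):
            raise StructureError(f"edge ({u}, {v}) missing from network")
    total_cost = sum(network.cost(u, v) for u, v in subnetwork.edges)
    total_prize = sum(network.prize(v) for v in subnetwork.vertices)
    return total_cost - total_prize


def brute_force_pcst(network: DrugNetwork, max_vertices: int = 12) -> Subnetwork:
    """Exact prize-collecting Steiner tree by exhaustive enumeration.

    Enumerates every vertex subset containing the terminals whose induced
    subgraph is connected, takes the MST of each, and returns the tree with
    the minimum objective (ties: fewer vertices, then lexicographic vertex
    set). Guarded to small instances; intended as a test oracle.
    """
    if network.n_vertices > max_vertices:
        raise ParameterError(
            f"brute force is guarded to {max_vertices} vertices, got {network.n_vertices}"
        )
    terminals = sorted(network.terminals)
    others = sorted(set(network.graph.nodes) - network.terminals)
    best: tuple[float, int, tuple[str, ...]] | None = None
    best_sub: Subnetwork | None = None
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            vset = tuple(sorted(terminals + list(extra)))
            induced = network.graph.subgraph(vset)
            if not nx.is_connected(induced):
                continue
            sub_net = DrugNetwork(
                graph=induced.copy(), terminals=network.terminals
            )
            mst = prim_mst(sub_net)
            tree = Subnetwork(vertices=frozenset(vset), edges=mst.edges, parent=network)
            obj = pcst_objective(tree, network)
            key = (obj, len(vset), vset)
            if best is None or key < best:
                best = key
                best_sub = tree
    assert best_sub is not None  # terminals themselves induce a candidate iff connected
    return best_sub


def select_best(
    subnetworks: Sequence[Subnetwork],
    network: DrugNetwork,
    superclass: Iterable[str],
) -> Subnetwork:
    """Pick the subnetwork with the highest Rand Index.

    Ties are broken by smaller vertex count (small subnetworks are preferable
    for repositioning analysis), then by smaller objective.
    """
    if not subnetworks:
        raise ParameterError("select_best needs a non-empty list")
    superclass = frozenset(superclass)

    def key(sub: Subnetwork):
        res = rand_index(sub, network, superclass)
        return (-res.rand_index, res.n_vertices, res.objective)

    return min(subnetworks, key=key)


def candidate_frequencies(
    selected: Sequence[Subnetwork],
    superclass: Iterable[str],
    threshold: int = 2,
) -> CandidateRanking:
    """Count occurrences of out-of-superclass drugs across selected subnetworks.

    ``candidates`` holds the drugs whose count reaches ``threshold`` (default
    2: drugs occurring more than once), ordered by descending frequency then
    drug id.
    """
    if threshold < 1:
        raise ParameterError("threshold must be at least 1")
    superclass = frozenset(superclass)
    counts: dict[str, int] = {}
    for sub in selected:
        for v in sub.vertices - superclass:
            counts[v] = counts.get(v, 0) + 1
    candidates = tuple(
        d for d, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if counts[d] >= threshold
    )
    return CandidateRanking(frequencies=counts, candidates=candidates, threshold=threshold)


@dataclass(frozen=True)
class SummaryStats:
    """Dispersion diagnostics of a family of networks (population convention).

    ``sd_vertex_prizes`` is the mean over networks of the population standard
    deviation of vertex prizes; ``sd_edge_costs`` the same for edge costs.
    The ``*_pct`` properties report the same values scaled by 100.
    """

    sd_vertex_prizes: float
    sd_edge_costs: float

    @property
    def sd_vertex_prizes_pct(self) -> float:
        return self.sd_vertex_prizes * 100.0

    @property
    def sd_edge_costs_pct(self) -> float:
        return self.sd_edge_costs * 100.0


def network_summary_stats(networks: Sequence[DrugNetwork]) -> SummaryStats:
    """Average prize and cost standard deviations across networks."""
    if not networks:
        raise ParameterError("need at least one network")
    sd_p = float(
        np.mean([np.std(list(net.prizes.values())) for net in networks])
    )
    sd_c = float(
        np.mean([np.std(list(net.costs.values())) for net in networks])
    )
    return SummaryStats(sd_vertex_prizes=sd_p, sd_edge_costs=sd_c)
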