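"""Physarum-inspired subnetwork identification (PSIA).

The solver mimics the adaptive flow network of *Physarum polycephalum*. One
terminal is drawn probabilistically as the sink; all remaining terminals
inject a flux I0 as sources. Each edge (i, j) carries a conductivity D_ij and
a prize-discounted net cost

    C_ij = c_ij - p_i/d_i - p_j/d_j + 2N,       N = max_k p_k,

which is strictly positive whenever c_ij > 0 (each p/d term is at most N).
Given conductances g = D/C, vertex pressures solve the network Poisson
(Kirchhoff) equation

    sum_{i ~ j} g_ij (Pr_i - Pr_j) = -I0          at a source,
                                   = (|T|-1) I0   at the sink,
                                   = 0            elsewhere,

with the sink pressure pinned to 0. Edge fluxes Q_ij = g_ij (Pr_i - Pr_j)
then feed the conductivity adaptation

    D(k+1) = D(k) + alpha |Q(k)| - mu D(k),

which reinforces edges that carry flux and decays the rest. Edges whose
conductivity falls below a threshold epsilon are cut, except when the cut
would disconnect a terminal from the sink (a feasibility guard: the output
must span all terminals and removed edges never return). After K iterations
the connected component containing the sink is reduced to its minimum
spanning tree under the original costs, which is the identified subnetwork.

Sink selection favours terminals with a small total incident edge cost:
ranking terminals by l(i) = total cost of incident edges with
l(1) <= ... <= l(|T|), the rank-i terminal is drawn with probability
l(|T|-i+1) / sum_j l(j).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from physteiner.dsn import DrugNetwork, Subnetwork, edge_key
from physteiner.errors import ParameterError, StructureError
from physteiner.sparsify import prim_mst

__all__ = [
    "PhysarumParams",
    "PhysarumState",
    "sink_probabilities",
    "edge_net_cost",
    "solve_pressures",
    "compute_flux",
    "update_conductivities",
    "cut_edges",
    "kirchhoff_residuals",
    "psia_identify",
    "psia_multi",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class PhysarumParams:
    """Tunable constants of the Physarum dynamics.

    alpha scales flux reinforcement, mu in (0, 1) is the decay rate, epsilon
    is the conductivity cut threshold, n_iterations is the number K of
    update/cut rounds, source_flux is the injection I0 per source, and
    init_conductivity_range bounds the uniform random conductivity
    initialisation (randomness keeps the Poisson system non-singular when
    net costs are nearly uniform). ``cut_every_iteration`` switches between
    cutting after every conductivity update (default) and cutting only once
    after the final update.
    """

    alpha: float = 1.0
    mu: float = 0.3
    epsilon: float = 0.01
    n_iterations: int = 50
    source_flux: float = 1.0
    seed: int = 0
    init_conductivity_range: tuple[float, float] = (0.5, 1.5)
    cut_every_iteration: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0 or not 0 < self.mu < 1:
            raise ParameterError("require alpha > 0 and 0 < mu < 1")
        if self.epsilon <= 0 or self.source_flux <= 0:
            raise ParameterError("epsilon and source_flux must be positive")
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be at least 1")
        low, high = self.init_conductivity_range
        if not 0 < low < high:
            raise ParameterError("init_conductivity_range must satisfy 0 < low < high")


@dataclass
class PhysarumState:
    """Mutable per-iteration state of one PSIA run.

    ``graph`` is the surviving working graph (edge attribute ``cost``); the
    dictionaries mirror its current edge set.
    """

    graph: nx.Graph
    sink: str
    sources: frozenset[str]
    prize_max: float
    source_flux: float
    conductivities: dict[Edge, float]
    net_costs: dict[Edge, float] = field(default_factory=dict)
    pressures: dict[str, float] = field(default_factory=dict)
    fluxes: dict[Edge, float] = field(default_factory=dict)
    degrees: dict[str, int] = field(default_factory=dict)
    iteration: int = 0

    @property
    def terminals(self) -> frozenset[str]:
        return self.sources | {self.sink}


def sink_probabilities(network: DrugNetwork) -> dict[str, float]:
    """Probability of each terminal being chosen as the sink.

    Terminals are ranked by their total incident edge cost l(i) (ascending,
    ties by vertex id) and the rank-i terminal receives the rank-reversed
    weight l(|T|-i+1) / sum_j l(j): the cheapest-attached terminal is the
    likeliest sink.
    """
    g = network.graph
    loads: list[tuple[float, str]] = []
    for t in sorted(network.terminals):
        if g.degree(t) == 0:
            raise StructureError(f"terminal {t!r} is isolated")
        loads.append((sum(d["cost"] for _, _, d in g.edges(t, data=True)), t))
    loads.sort()
    total = sum(l for l, _ in loads)
    n = len(loads)
    return {loads[i][1]: loads[n - 1 - i][0] / total for i in range(n)}


def _net_costs(
    graph: nx.Graph, prizes: Mapping[str, float], prize_max: float
) -> dict[Edge, float]:
    deg = dict(graph.degree())
    return {
        edge_key(u, v): d["cost"] - prizes[u] / deg[u] - prizes[v] / deg[v] + 2.0 * prize_max
        for u, v, d in graph.edges(data=True)
    }


def edge_net_cost(network: DrugNetwork) -> dict[Edge, float]:
    """Prize-discounted net cost C_ij = c_ij - p_i/d_i - p_j/d_j + 2N per edge."""
    prizes = network.prizes
    return _net_costs(network.graph, prizes, max(prizes.values(), default=0.0))


def solve_pressures(state: PhysarumState) -> dict[str, float]:
    """Solve the network Poisson equation on the sink's component.

    The sink pressure is pinned to 0 and the reduced symmetric positive
    definite system over the remaining component vertices is solved with a
    sparse direct factorisation. Vertices outside the sink's component get
    pressure 0 (they carry no source/sink flux and are dropped at
    finalisation).
    """
    g = state.graph
    comp = nx.node_connected_component(g, state.sink)
    stranded = state.sources - comp
    if stranded:
        raise StructureError(f"source terminal(s) cut off from sink: {sorted(stranded)[:3]}")
    nodes = sorted(comp)
    idx = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    diag = np.zeros(n)
    for u, v in g.subgraph(comp).edges():
        e = edge_key(u, v)
        gcond = state.conductivities[e] / state.net_costs[e]
        a, b = idx[u], idx[v]
        rows.extend((a, b))
        cols.extend((b, a))
        vals.extend((-gcond, -gcond))
        diag[a] += gcond
        diag[b] += gcond
    lap = sp.csr_array(
        (
            np.concatenate([np.asarray(vals), diag]),
            (
                np.concatenate([np.asarray(rows, dtype=np.int64), np.arange(n)]),
                np.concatenate([np.asarray(cols, dtype=np.int64), np.arange(n)]),
            ),
        ),
        shape=(n, n),
    )
    # Conservation written as (L Pr)_j = +I0 at sources, -(|T|-1) I0 at sink.
    b_vec = np.zeros(n)
    i0 = state.source_flux
    for s in state.sources:
        b_vec[idx[s]] = i0
    b_vec[idx[state.sink]] = -len(state.sources) * i0
    keep = np.array([k for k in range(n) if k != idx[state.sink]], dtype=np.int64)
    pr = np.zeros(n)
    if keep.size:
        reduced = lap[np.ix_(keep, keep)]
        pr[keep] = spla.spsolve(sp.csc_matrix(reduced), b_vec[keep])
    pressures = {v: 0.0 for v in g.nodes}
    for v, k in idx.items():
        pressures[v] = float(pr[k])
    state.pressures = pressures
    return pressures


def compute_flux(state: PhysarumState) -> dict[Edge, float]:
    """Edge fluxes Q_ij = (D/C)(Pr_i - Pr_j), oriented from the smaller vertex id.

    Flipping the orientation flips the sign. Edges outside the sink's
    component see equal (zero) pressures and carry zero flux.
    """
    fluxes = {
        e: (d / state.net_costs[e])
        * (state.pressures.get(e[0], 0.0) - state.pressures.get(e[1], 0.0))
        for e, d in state.conductivities.items()
    }
    state.fluxes = fluxes
    return fluxes


def update_conductivities(
    state: PhysarumState, params: PhysarumParams
) -> dict[Edge, float]:
    """Apply D <- D + alpha |Q| - mu D elementwise (values may drop below epsilon)."""
    new = {
        e: d + params.alpha * abs(state.fluxes[e]) - params.mu * d
        for e, d in state.conductivities.items()
    }
    state.conductivities = new
    return new


def cut_edges(state: PhysarumState, epsilon: float) -> list[Edge]:
    """Remove edges whose conductivity fell below ``epsilon``.

    A candidate is skipped when its removal would disconnect some terminal
    from the sink (feasibility guard). Candidates are processed in ascending
    (conductivity, edge) order; removed edges never return.
    """
    g = state.graph
    terminals = state.terminals
    candidates = sorted((d, e) for e, d in state.conductivities.items() if d < epsilon)
    removed: list[Edge] = []
    for _, (u, v) in candidates:
        cost = g.edges[u, v]["cost"]
        g.remove_edge(u, v)
        if terminals <= nx.node_connected_component(g, state.sink):
            removed.append((u, v))
            del state.conductivities[(u, v)]
            state.net_costs.pop((u, v), None)
            state.fluxes.pop((u, v), None)
        else:
            g.add_edge(u, v, cost=cost)
    return removed


def kirchhoff_residuals(state: PhysarumState) -> dict[str, float]:
    """Per-vertex residual of flux conservation after a pressure solve.

    For each vertex j in the sink's component the residual is
    ``sum_i g_ij (Pr_i - Pr_j) - rhs_j`` with rhs_j = -I0 at sources,
    (|T|-1) I0 at the sink and 0 elsewhere.
    """
    g = state.graph
    comp = nx.node_connected_component(g, state.sink)
    net = {v: 0.0 for v in comp}
    for e, d in state.conductivities.items():
        u, v = e
        if u in comp and v in comp:
            q = (d / state.net_costs[e]) * (state.pressures[u] - state.pressures[v])
            net[u] -= q  # contribution g_uv (Pr_v - Pr_u) to vertex u's row
            net[v] += q
    i0 = state.source_flux
    res: dict[str, float] = {}
    for v in comp:
        if v in state.sources:
            rhs = -i0
        elif v == state.sink:
            rhs = len(state.sources) * i0
        else:
            rhs = 0.0
        res[v] = net[v] - rhs
    return res


def init_state(
    network: DrugNetwork, params: PhysarumParams, rng: np.random.Generator
) -> PhysarumState:
    """Draw the sink, initialise random conductivities, return a fresh state."""
    probs = sink_probabilities(network)
    terminals = sorted(probs)
    p = np.array([probs[t] for t in terminals])
    sink = terminals[int(rng.choice(len(terminals), p=p / p.sum()))]
    g = network.graph.copy()
    low, high = params.init_conductivity_range
    edges = sorted(edge_key(u, v) for u, v in g.edges)
    cond = {e: float(c) for e, c in zip(edges, rng.uniform(low, high, len(edges)))}
    return PhysarumState(
        graph=g,
        sink=sink,
        sources=frozenset(network.terminals) - {sink},
        prize_max=max(network.prizes.values(), default=0.0),
        source_flux=params.source_flux,
        conductivities=cond,
    )


def psia_identify(network: DrugNetwork, params: PhysarumParams) -> Subnetwork:
    """Run one PSIA pass and return the identified terminal-spanning tree.

    Net costs are recomputed every iteration because edge cuts change vertex
    degrees (and hence the p/d prize discounts). After the K update/cut
    rounds the sink's connected component is reduced to its MST under the
    original edge costs; vertices outside that component are dropped.
    """
    if len(network.terminals) < 2:
        raise StructureError("PSIA needs at least 2 terminals")
    if not nx.is_connected(network.graph):
        raise StructureError("PSIA requires a connected network")
    rng = np.random.default_rng(params.seed)
    state = init_state(network, params, rng)
    prizes = network.prizes
    for k in range(params.n_iterations):
        state.iteration = k
        state.degrees = dict(state.graph.degree())
        state.net_costs = _net_costs(state.graph, prizes, state.prize_max)
        solve_pressures(state)
        compute_flux(state)
        update_conductivities(state, params)
        if params.cut_every_iteration or k == params.n_iterations - 1:
            cut_edges(state, params.epsilon)
    comp = nx.node_connected_component(state.graph, state.sink)
    comp_graph = nx.Graph()
    comp_graph.add_nodes_from((v, network.graph.nodes[v]) for v in comp)
    for u, v, d in state.graph.subgraph(comp).edges(data=True):
        comp_graph.add_edge(u, v, cost=d["cost"])
    mst = prim_mst(DrugNetwork(graph=comp_graph, terminals=network.terminals))
    return Subnetwork(vertices=frozenset(comp), edges=mst.edges, parent=network)


def psia_multi(
    network: DrugNetwork, params: PhysarumParams, n_runs: int
) -> list[Subnetwork]:
    """Run PSIA ``n_runs`` times with per-run seeds derived from ``params.seed``.

    Each run's seed comes from ``SeedSequence([master, run_index])`` so runs
    share no RNG state and the list is reproducible from the master seed.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be at least 1")
    out = []
    for r in range(n_runs):
        derived = int(
            np.random.SeedSequence([params.seed, r]).generate_state(1)[0] % 2**31
        )
        out.append(psia_identify(network, replace(params, seed=derived)))
    return out
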