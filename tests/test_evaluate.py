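"""Rand Index scoring, exact enumeration oracle, selection and ranking."""

import pytest

from physteiner.dsn import Subnetwork
from physteiner.errors import InputError, ParameterError
from physteiner.evaluate import (
    brute_force_pcst,
    candidate_frequencies,
    network_summary_stats,
    pcst_objective,
    rand_index,
    rand_index_from_counts,
    select_best,
)
from physteiner.sparsify import prim_mst

from conftest import make_network, random_instance


def test_rand_index_from_counts_worked_examples():
    # 548 drugs, superclass 104: published-layout fixtures
    assert rand_index_from_counts(548, 104, 4, 9, 1) == pytest.approx(441 / 544 * 100)
    assert rand_index_from_counts(548, 104, 8, 19, 1) == pytest.approx(435 / 540 * 100)


def test_rand_index_perfect_partition_is_100():
    assert rand_index_from_counts(20, 4, 4, 4, 0) == pytest.approx(100.0)


def test_rand_index_set_count_agreement():
    """Set-based scoring agrees with the closed-form count formula and the
    four confusion categories tile the non-terminal vertices."""
    net = random_instance(4242)
    terminals = net.terminals
    vertices = sorted(net.graph.nodes)
    superclass = set(terminals) | set(vertices[:2])
    sub_vertices = set(terminals) | set(vertices[-2:])
    g = net.graph.subgraph(sub_vertices)
    import networkx as nx

    if not nx.is_connected(g):
        sub_vertices = set(vertices)  # fall back to the full vertex set
    sub_net = make_network(
        {v: net.prize(v) for v in sub_vertices},
        {e: c for e, c in net.costs.items() if set(e) <= sub_vertices},
        terminals,
    )
    tree = prim_mst(sub_net)
    sub = Subnetwork(vertices=frozenset(sub_vertices), edges=tree.edges, parent=net)
    res = rand_index(sub, net, superclass)
    assert res.rand_index == pytest.approx(
        rand_index_from_counts(
            len(vertices), len(superclass), len(terminals), len(sub_vertices), res.i_c
        )
    )
    fp = len(sub.vertices - terminals - superclass)
    fn = len((superclass - terminals) - sub.vertices)
    assert res.i_c + res.n_nc + fp + fn == len(vertices) - len(terminals)


def test_rand_index_requires_terminals_in_superclass():
    net = make_network(
        prizes={"a": 0, "b": 0, "c": 0},
        costs={("a", "b"): 1.0, ("b", "c"): 1.0},
        terminals={"a", "b"},
    )
    sub = Subnetwork(vertices=frozenset("ab"), edges=frozenset({("a", "b")}), parent=net)
    with pytest.raises(InputError):
        rand_index(sub, net, {"a"})  # terminal b missing from superclass


def test_pcst_objective_arithmetic():
    net = make_network(
        prizes={"a": 0.2, "b": 0.3, "c": 0.4},
        costs={("a", "b"): 1.0, ("b", "c"): 1.0},
        terminals={"a", "b"},
    )
    lone = Subnetwork(vertices=frozenset({"c"}), edges=frozenset(), parent=net)
    assert pcst_objective(lone, net) == pytest.approx(-0.4)
    pair = Subnetwork(
        vertices=frozenset({"a", "b"}), edges=frozenset({("a", "b")}), parent=net
    )
    assert pcst_objective(pair, net) == pytest.approx(0.5)
    # adding a vertex+edge whose cost is below its prize improves the objective
    bigger = Subnetwork(
        vertices=frozenset({"a", "b", "c"}),
        edges=frozenset({("a", "b"), ("b", "c")}),
        parent=net,
    )
    assert pcst_objective(bigger, net) == pytest.approx(0.5 + 1.0 - 0.4)


def test_brute_force_triangle_prefers_prized_path():
    net = make_network(
        prizes={"a": 0.0, "b": 0.0, "c": 0.5},
        costs={("a", "b"): 1.0, ("a", "c"): 0.4, ("b", "c"): 0.4},
        terminals={"a", "b"},
    )
    best = brute_force_pcst(net)
    assert best.edges == frozenset({("a", "c"), ("b", "c")})
    assert pcst_objective(best, net) == pytest.approx(0.3)


def test_brute_force_all_terminals_is_global_mst():
    net = random_instance(31)
    all_t = make_network(net.prizes, net.costs, set(net.graph.nodes))
    best = brute_force_pcst(all_t)
    assert best.vertices == frozenset(all_t.graph.nodes)
    assert best.total_cost() == pytest.approx(prim_mst(all_t).total_cost())


def test_brute_force_guard():
    with pytest.raises(ParameterError):
        brute_force_pcst(random_instance(1), max_vertices=3)


def test_select_best_prefers_high_ri_then_small():
    net = make_network(
        prizes={v: 0.0 for v in "abcde"},
        costs={
            ("a", "b"): 0.5,
            ("b", "c"): 0.5,
            ("c", "d"): 0.5,
            ("d", "e"): 0.5,
            ("a", "e"): 0.5,
        },
        terminals={"a", "b"},
    )
    superclass = {"a", "b", "c"}
    small = Subnetwork(
        vertices=frozenset("ab"), edges=frozenset({("a", "b")}), parent=net
    )
    big = Subnetwork(
        vertices=frozenset("abcde"),
        edges=frozenset({("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")}),
        parent=net,
    )
    # small: I_c=0, N_nc=2 -> RI = 2/3; big: I_c=1, N_nc=0 -> RI = 1/3
    assert select_best([big, small], net, superclass) is small
    assert select_best([small], net, superclass) is small
    # identical RI (both 2/3): the smaller vertex set wins
    four = Subnetwork(
        vertices=frozenset("abcd"),
        edges=frozenset({("a", "b"), ("b", "c"), ("c", "d")}),
        parent=net,
    )  # I_c=1 (c), N_nc=1 (e)
    two = Subnetwork(
        vertices=frozenset("ab"), edges=frozenset({("a", "b")}), parent=net
    )  # I_c=0, N_nc=2 (d, e)
    chosen = select_best([four, two], net, superclass)
    assert chosen is two


def _sub(net, vertices):
    return Subnetwork(vertices=frozenset(vertices), edges=frozenset(), parent=net)


def test_candidate_frequencies_threshold_and_order():
    net = make_network(
        prizes={v: 0.0 for v in "abcxyz"},
        costs={("a", "b"): 0.5},
        terminals={"a", "b"},
    )
    superclass = {"a", "b", "c"}
    subs = [
        _sub(net, {"a", "b", "x"}),
        _sub(net, {"a", "b", "x", "y"}),
        _sub(net, {"a", "b", "x", "z"}),
    ]
    ranking = candidate_frequencies(subs, superclass, threshold=2)
    assert ranking.frequencies == {"x": 3, "y": 1, "z": 1}
    assert ranking.candidates == ("x",)
    all_in = candidate_frequencies([_sub(net, {"a", "b", "c"})], superclass)
    assert all_in.frequencies == {} and all_in.candidates == ()


def test_summary_stats_population_convention():
    flat = make_network(
        prizes={"a": 0.3, "b": 0.3}, costs={("a", "b"): 1.0}, terminals={"a", "b"}
    )
    assert network_summary_stats([flat]).sd_vertex_prizes == pytest.approx(0.0)
    spread = make_network(
        prizes={"a": 0.0, "b": 1.0}, costs={("a", "b"): 1.0}, terminals={"a", "b"}
    )
    stats = network_summary_stats([spread])
    assert stats.sd_vertex_prizes == pytest.approx(0.5)
    assert stats.sd_vertex_prizes_pct == pytest.approx(50.0)
    both = network_summary_stats([spread, spread])
    assert both.sd_vertex_prizes == pytest.approx(0.5)
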