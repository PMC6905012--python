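import io
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from cnakit.correlation import Edge
from cnakit.data_io import AnalysisConfig, VariableGroup
from cnakit.fixtures import IMMUNE_GROUP_MAP, immune_fixture_edges
from cnakit.network_metrics import (
    NetworkSummary,
    betweenness_centrality,
    build_network,
    collapse_to_group_level,
    detect_hubs,
    group_summary,
    induced_group_subnetwork,
    network_density,
    node_degree,
    node_metrics,
    plot_group_collapsed,
    write_graphml,
    write_group_summaries,
)
from _oracles import (
    brute_force_betweenness,
    normalized_brute_force_betweenness,
    random_graph_adjacency,
)


def _net_from_adjacency(adj):
    gm = {v: "g" for v in adj}
    edges = []
    seen = set()
    for u in adj:
        for v in adj[u]:
            if (min(u, v), max(u, v)) not in seen:
                seen.add((min(u, v), max(u, v)))
                edges.append(Edge(u, v, 0.9, True))
    return build_network(edges, gm)


# -- construction -----------------------------------------------------------


def test_empty_edge_list():
    net = build_network([], {})
    assert net.n_nodes == 0 and net.n_edges == 0


def test_single_edge():
    net = build_network([Edge("a", "b", 0.8, True)], {"a": "g", "b": "g"})
    assert net.nodes == {"a", "b"}
    assert node_degree(net) == {"a": 1, "b": 1}


def test_immune_fixture_shape(immune_net):
    assert immune_net.n_nodes == 8
    assert immune_net.n_edges == 8


def test_duplicate_edge_rejected():
    edges = [Edge("a", "b", 0.8, True), Edge("b", "a", 0.9, True)]
    with pytest.raises(ValueError, match="duplicate"):
        build_network(edges, {"a": "g", "b": "g"})


def test_endpoint_without_group_rejected():
    with pytest.raises(ValueError, match="group"):
        build_network([Edge("a", "b", 0.8, True)], {"a": "g"})


def test_no_isolated_nodes(rng):
    # nodes are exactly edge endpoints, so min degree is 1 by construction
    adj = random_graph_adjacency(rng, 9, 0.3)
    net = _net_from_adjacency(adj)
    assert all(d >= 1 for d in node_degree(net).values())


# -- induced subnetwork and collapse ---------------------------------------


def _mixed_net():
    gm = {"a1": "G", "a2": "G", "a3": "G", "a4": "G", "b1": "H", "b2": "H"}
    edges = [
        Edge("a1", "a2", 0.8, True),
        Edge("a2", "a3", 0.75, True),
        Edge("a3", "a4", -0.9, True),
        Edge("a1", "b1", 0.7, False),
        Edge("a4", "b2", 0.85, False),
    ]
    return build_network(edges, gm)


def test_induced_subnetwork_counts():
    net = _mixed_net()
    sub = induced_group_subnetwork(net, "G")
    assert sub.n_edges == 3
    assert sub.nodes == {"a1", "a2", "a3", "a4"}


def test_induced_subnetwork_cross_group_only():
    gm = {"a": "G", "b": "H"}
    net = build_network([Edge("a", "b", 0.8, False)], gm)
    for g in ("G", "H"):
        sub = induced_group_subnetwork(net, g)
        assert sub.n_nodes == 0 and sub.n_edges == 0


def test_induced_subnetwork_closure(immune_net):
    sub = induced_group_subnetwork(immune_net, "immune_cell")
    assert sub.nodes == immune_net.nodes
    assert sub.n_edges == immune_net.n_edges


def test_induced_unknown_group():
    with pytest.raises(ValueError, match="unknown group"):
        induced_group_subnetwork(_mixed_net(), "nope")


def test_collapse_three_edges_one_connector():
    gm = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
    edges = [
        Edge("a1", "b1", 0.8, False),
        Edge("a2", "b2", 0.9, False),
        Edge("a3", "b3", -0.7, False),
    ]
    gln = collapse_to_group_level(build_network(edges, gm))
    assert gln.connectors == {("A", "B"): 3}
    assert gln.has_connector("B", "A")


def test_collapse_within_group_counts():
    gln = collapse_to_group_level(_mixed_net())
    assert gln.within_group_edge_counts == {"G": 3, "H": 0}
    assert gln.connectors == {("G", "H"): 2}


def test_collapse_matches_raw_edge_reconstruction(rng):
    # collapse correctness: connectors reconstructed from the raw edge list
    names = [f"b{i}" for i in range(12)]
    gm = {b: ["X", "Y", "Z"][i % 3] for i, b in enumerate(names)}
    edges = []
    for _ in range(15):
        i, j = rng.choice(12, size=2, replace=False)
        e = Edge(names[i], names[j], 0.8, gm[names[i]] == gm[names[j]])
        if e.pair not in {x.pair for x in edges}:
            edges.append(e)
    net = build_network(edges, gm)
    gln = collapse_to_group_level(net)
    expected: dict = {}
    for e in edges:
        ga, gb = gm[e.a], gm[e.b]
        if ga != gb:
            key = tuple(sorted((ga, gb)))
            expected[key] = expected.get(key, 0) + 1
    assert gln.connectors == expected


# -- degree -----------------------------------------------------------------


def test_star_degrees():
    gm = {c: "g" for c in "cabde"}
    edges = [Edge("c", leaf, 0.9, True) for leaf in "abde"]
    deg = node_degree(build_network(edges, gm))
    assert deg["c"] == 4
    assert all(deg[leaf] == 1 for leaf in "abde")


def test_immune_fixture_cytotoxic_degree(immune_net):
    # incident printed edges: Treg, Th1, T cells, CD8
    assert node_degree(immune_net)["Cytotoxic_cells"] == 4


def test_empty_network_degree():
    assert node_degree(build_network([], {})) == {}


def test_degree_sum_equals_twice_edges(rng):
    for _ in range(20):
        adj = random_graph_adjacency(rng, int(rng.integers(3, 10)), 0.4)
        net = _net_from_adjacency(adj)
        assert sum(node_degree(net).values()) == 2 * net.n_edges


# -- betweenness ------------------------------------------------------------


def test_path_center_bc_one():
    gm = {"a": "g", "b": "g", "c": "g"}
    net = build_network([Edge("a", "b", 0.8, True), Edge("b", "c", 0.8, True)], gm)
    assert betweenness_centrality(net)["b"] == pytest.approx(1.0)


def test_four_cycle_bc_one_sixth():
    gm = {c: "g" for c in "abcd"}
    edges = [
        Edge("a", "b", 0.8, True),
        Edge("b", "c", 0.8, True),
        Edge("c", "d", 0.8, True),
        Edge("d", "a", 0.8, True),
    ]
    net = build_network(edges, gm)
    bc = betweenness_centrality(net)
    # each opposite pair has 2 shortest paths -> raw 1/2, normalized /3
    assert all(v == pytest.approx(1 / 6) for v in bc.values())


def test_immune_fixture_treg_bc(immune_net):
    raw = betweenness_centrality(immune_net, normalized=False)
    norm = betweenness_centrality(immune_net, normalized=True)
    assert raw["Treg"] == pytest.approx(12.0, abs=1e-12)
    assert norm["Treg"] == pytest.approx(12 / 21, abs=1e-12)


def test_immune_fixture_matches_oracle(immune_net):
    adj = {n: set(immune_net.graph.neighbors(n)) for n in immune_net.nodes}
    oracle_raw = brute_force_betweenness(adj)
    raw = betweenness_centrality(immune_net, normalized=False)
    for n in adj:
        assert raw[n] == pytest.approx(float(oracle_raw[n]), abs=1e-12)


def test_small_component_scores_zero():
    gm = {"a": "g", "b": "g"}
    net = build_network([Edge("a", "b", 0.9, True)], gm)
    assert betweenness_centrality(net) == {"a": 0.0, "b": 0.0}


def test_bc_oracle_equivalence_random_graphs(rng):
    # a modest sample here; the full >= 200-graph sweep runs in acceptance
    for _ in range(40):
        n = int(rng.integers(3, 11))
        p = float(rng.uniform(0.1, 0.9))
        adj = random_graph_adjacency(rng, n, p)
        adj = {v: nb for v, nb in adj.items() if nb}
        if not adj:
            continue
        net = _net_from_adjacency(adj)
        expected = normalized_brute_force_betweenness(
            {v: set(net.graph.neighbors(v)) for v in net.nodes}
        )
        got = betweenness_centrality(net)
        for v, e in expected.items():
            assert got[v] == pytest.approx(e, abs=1e-12)


def test_bc_in_unit_interval(rng):
    adj = random_graph_adjacency(rng, 10, 0.5)
    net = _net_from_adjacency(adj)
    assert all(0.0 <= v <= 1.0 for v in betweenness_centrality(net).values())


# -- density ----------------------------------------------------------------


def test_density_eleven_edges_sixteen_universe():
    assert network_density(11, 16) == pytest.approx(11 / 120)
    assert round(network_density(11, 16), 2) == 0.09


def test_density_seven_edges_sixteen_universe():
    assert network_density(7, 16) == pytest.approx(7 / 120)
    assert round(network_density(7, 16), 2) == 0.06


def test_density_complete_graph():
    gm = {c: "g" for c in "abcd"}
    edges = [
        Edge(a, b, 0.9, True)
        for i, a in enumerate("abcd")
        for b in "abcd"[i + 1 :]
    ]
    net = build_network(edges, gm)
    assert network_density(net, 4) == pytest.approx(1.0)


def test_density_errors():
    with pytest.raises(ValueError):
        network_density(1, 1)
    with pytest.raises(ValueError):
        network_density(10, 4)  # > C(4,2) edges impossible
    assert network_density(0, 1) == 0.0  # empty network has density 0


# -- hubs -------------------------------------------------------------------


def test_reported_hub_scores_detected():
    scores = {
        "Treg": 0.22,
        "Neutrophils": 0.20,
        "Cytotoxic_cells": 0.15,
        "NK_cells": 0.08,
        "T_cells": 0.0,
    }
    assert detect_hubs(scores, 0.1) == ["Treg", "Neutrophils", "Cytotoxic_cells"]


def test_no_hubs_when_all_zero():
    assert detect_hubs({"a": 0.0, "b": 0.0}, 0.1) == []


def test_boundary_score_not_a_hub():
    assert detect_hubs({"a": 0.1}, 0.1) == []
    assert detect_hubs({"a": 0.10000001}, 0.1) == ["a"]


# -- group summary ----------------------------------------------------------


def _fixture_summary(immune_net, n_extra_edges=3, **cfg_kwargs):
    """Immune fixture + extra cross-group edges so scope settings matter."""
    roster16 = VariableGroup("immune_cell", tuple(IMMUNE_GROUP_MAP) + tuple(
        f"immune_extra_{i}" for i in range(16 - len(IMMUNE_GROUP_MAP))
    ))
    cfg = AnalysisConfig(**cfg_kwargs)
    return group_summary(immune_net, "immune_cell", roster16, cfg)


def test_summary_roster_universe_two_dp(immune_net):
    s = _fixture_summary(immune_net)
    assert s.edge_count == 8
    assert s.density == pytest.approx(8 / 120)
    assert s.hub_names[0] == "Treg"
    assert s.hub_count == 3  # Treg, Neutrophils, Cytotoxic all > 0.1


def test_summary_connected_universe(immune_net):
    s = _fixture_summary(immune_net, density_universe="connected_nodes")
    assert s.density == pytest.approx(8 / 28)  # 8 nodes connected


def test_summary_empty_group():
    gm = {"a": "G", "b": "H"}
    net = build_network([Edge("a", "b", 0.8, False)], gm)
    s = group_summary(net, "G", VariableGroup("G", ("a",)), AnalysisConfig())
    assert s.edge_count == 0 and s.density == 0.0 and s.hub_count == 0


def test_summary_invariant():
    with pytest.raises(ValueError):
        NetworkSummary("g", 1, 0.5, 2, ("only_one",))


def test_node_metrics_ordering(immune_net):
    rows = node_metrics(immune_net)
    assert rows[0].biomarker == "Treg"
    assert rows[0].is_hub
    bcs = [r.bc for r in rows]
    assert bcs == sorted(bcs, reverse=True)


# -- exporters --------------------------------------------------------------


def test_graphml_round_trip(immune_net, tmp_path):
    path = tmp_path / "net.graphml"
    write_graphml(immune_net, path)
    back = nx.read_graphml(path)
    assert set(back.nodes) == immune_net.nodes
    assert back.nodes["Treg"]["group"] == "immune_cell"
    assert back.nodes["Treg"]["is_hub"] is True
    assert back.edges[("Treg", "Neutrophils")]["rho"] == pytest.approx(0.73)


def test_summary_writer_two_dp(tmp_path):
    s = NetworkSummary("immune_cell", 11, 11 / 120, 3, ("a", "b", "c"))
    buf = io.StringIO()
    write_group_summaries([s], buf)
    lines = buf.getvalue().splitlines()
    assert lines[0] == "network,edge_count,density,hub_count"
    assert lines[1] == "immune_cell,11,0.09,3"


def test_plot_smoke(immune_net, tmp_path):
    out = tmp_path / "net.png"
    plot_group_collapsed(immune_net, out)
    assert out.stat().st_size > 0
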