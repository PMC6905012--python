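"""Biomarker network construction and graph metrics.

The network keeps only biomarkers with at least one supra-threshold
correlation.  Metrics follow the combinatorial definitions: degree is the
incident-edge count, betweenness centrality is the standard fractional
shortest-path accumulation on the unweighted graph normalized by
(n-1)(n-2)/2, and density is edge count over the possible edges of a
stated node universe.  Hubs are nodes with normalized betweenness
strictly above a cutoff (0.1 by default).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TextIO, Union

import networkx as nx

from .correlation import Edge
from .data_io import AnalysisConfig, VariableGroup

__all__ = [
    "BiomarkerNetwork",
    "GroupLevelNetwork",
    "NodeMetrics",
    "NetworkSummary",
    "build_network",
    "induced_group_subnetwork",
    "collapse_to_group_level",
    "node_degree",
    "betweenness_centrality",
    "network_density",
    "detect_hubs",
    "node_metrics",
    "group_summary",
    "write_graphml",
    "write_group_summaries",
    "plot_group_collapsed",
]


@dataclass
class BiomarkerNetwork:
    """Undirected graph of supra-threshold biomarker correlations.

    Nodes are exactly the endpoints of the given edges, so every node has
    degree >= 1 by construction.  Node attribute ``group`` and edge
    attribute ``rho`` are stored on the underlying :class:`networkx.Graph`.
    """

    graph: nx.Graph
    provenance: AnalysisConfig | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[Edge]:
        out = []
        for a, b, d in self.graph.edges(data=True):
            out.append(Edge(a, b, d["rho"], d["within_group"]))
        return sorted(out, key=lambda e: e.pair)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def group_of(self, biomarker: str) -> str:
        return self.graph.nodes[biomarker]["group"]

    def groups_present(self) -> set[str]:
        return {d["group"] for _, d in self.graph.nodes(data=True)}


@dataclass(frozen=True)
class GroupLevelNetwork:
    """Collapsed view: variable groups as nodes.

    A connector (G1, G2) exists iff at least one biomarker edge spans the
    two groups; its count records how many such edges exist (the rendered
    collapsed view shows a single line regardless of the count).
    """

    group_nodes: frozenset[str]
    connectors: dict[tuple[str, str], int]
    within_group_edge_counts: dict[str, int]

    def has_connector(self, g1: str, g2: str) -> bool:
        return tuple(sorted((g1, g2))) in self.connectors


@dataclass(frozen=True)
class NodeMetrics:
    biomarker: str
    group: str
    degree: int
    bc: float
    is_hub: bool


@dataclass(frozen=True)
class NetworkSummary:
    """Per-variable-group row: edge count, density, hubs."""

    group: str
    edge_count: int
    density: float
    hub_count: int
    hub_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.hub_count != len(self.hub_names):
            raise ValueError("hub_count must equal len(hub_names)")


def build_network(
    edges: Sequence[Edge],
    group_map: Mapping[str, str],
    provenance: AnalysisConfig | None = None,
) -> BiomarkerNetwork:
    """Assemble the thresholded graph from an edge list.

    Nodes are exactly the edge endpoints; isolated biomarkers never enter.
    Duplicate unordered pairs and endpoints without a group assignment are
    hard errors.
    """
    g = nx.Graph()
    seen: set[tuple[str, str]] = set()
    for e in edges:
        if e.pair in seen:
            raise ValueError(f"duplicate edge {e.pair}")
        seen.add(e.pair)
        for endpoint in e.pair:
            if endpoint not in group_map:
                raise ValueError(f"edge endpoint {endpoint!r} has no group assignment")
        g.add_node(e.a, group=group_map[e.a])
        g.add_node(e.b, group=group_map[e.b])
        g.add_edge(e.a, e.b, rho=e.rho, within_group=e.within_group)
    return BiomarkerNetwork(graph=g, provenance=provenance)


def induced_group_subnetwork(net: BiomarkerNetwork, group: str) -> BiomarkerNetwork:
    """Within-group edges of one variable group and their endpoints.

    Biomarkers of the group that only have cross-group edges do not appear
    (they are isolated in the induced view).
    """
    known = net.groups_present()
    if net.n_nodes > 0 and group not in known:
        raise ValueError(f"unknown group {group!r}; present: {sorted(known)}")
    g = nx.Graph()
    for a, b, d in net.graph.edges(data=True):
        if d["within_group"] and net.group_of(a) == group:
            g.add_node(a, group=group)
            g.add_node(b, group=group)
            g.add_edge(a, b, **d)
    return BiomarkerNetwork(graph=g, provenance=net.provenance)


def collapse_to_group_level(net: BiomarkerNetwork) -> GroupLevelNetwork:
    """Collapse biomarker edges to the group-level meta-graph."""
    connectors: dict[tuple[str, str], int] = {}
    within: dict[str, int] = {g: 0 for g in net.groups_present()}
    for a, b, d in net.graph.edges(data=True):
        ga, gb = net.group_of(a), net.group_of(b)
        if ga == gb:
            within[ga] += 1
        else:
            key = tuple(sorted((ga, gb)))
            connectors[key] = connectors.get(key, 0) + 1
    return GroupLevelNetwork(
        group_nodes=frozenset(net.groups_present()),
        connectors=connectors,
        within_group_edge_counts=within,
    )


def node_degree(net: BiomarkerNetwork) -> dict[str, int]:
    """Incident-edge count per node."""
    return {n: int(d) for n, d in net.graph.degree()}


def betweenness_centrality(
    net: BiomarkerNetwork, normalized: bool = True
) -> dict[str, float]:
    """Fractional shortest-path betweenness on the unweighted graph.

    For each node v, sum over unordered pairs {s, t} (s != t != v) of
    sigma_st(v) / sigma_st, where sigma_st counts shortest paths.  The
    normalized form divides by (n-1)(n-2)/2 with n the node count of the
    graph being scored; nodes in components of size <= 2 score 0.
    """
    if net.n_nodes == 0:
        return {}
    return {
        n: float(v)
        for n, v in nx.betweenness_centrality(
            net.graph, normalized=normalized, weight=None
        ).items()
    }


def network_density(net_or_edge_count, universe_size: int) -> float:
    """Edge count over the possible edges of a ``universe_size`` universe.

    The universe is stated by the caller: either the full measured roster
    of a group (default convention) or its connected node count.  An empty
    network has density 0 regardless of universe.
    """
    if isinstance(net_or_edge_count, BiomarkerNetwork):
        edge_count = net_or_edge_count.n_edges
    else:
        edge_count = int(net_or_edge_count)
    if edge_count == 0:
        return 0.0
    if universe_size < 2:
        raise ValueError(f"universe_size must be >= 2, got {universe_size}")
    possible = universe_size * (universe_size - 1) // 2
    if edge_count > possible:
        raise ValueError(
            f"{edge_count} edges impossible in a universe of {universe_size}"
        )
    return edge_count / possible


def detect_hubs(
    bc_scores: Mapping[str, float], hub_bc_threshold: float = 0.1
) -> list[str]:
    """Biomarkers with normalized betweenness strictly above the cutoff.

    Returned in descending score order (ties broken lexicographically for
    deterministic reports).  A score exactly at the cutoff is not a hub.
    """
    hubs = [b for b, s in bc_scores.items() if s > hub_bc_threshold]
    hubs.sort(key=lambda b: (-bc_scores[b], b))
    return hubs


def node_metrics(
    net: BiomarkerNetwork, config: AnalysisConfig | None = None
) -> list[NodeMetrics]:
    """Degree, betweenness and hub flag per node of the given graph."""
    cfg = config or net.provenance or AnalysisConfig()
    deg = node_degree(net)
    bc = betweenness_centrality(net, normalized=True)
    hubs = set(detect_hubs(bc, cfg.hub_bc_threshold))
    rows = [
        NodeMetrics(
            biomarker=n,
            group=net.group_of(n),
            degree=deg[n],
            bc=bc[n],
            is_hub=n in hubs,
        )
        for n in net.nodes
    ]
    rows.sort(key=lambda m: (-m.bc, -m.degree, m.biomarker))
    return rows


def group_summary(
    net: BiomarkerNetwork,
    group: str,
    roster: VariableGroup,
    config: AnalysisConfig | None = None,
) -> NetworkSummary:
    """The per-group summary row: edge count, density, hubs.

    Density uses the full measured roster as universe under the default
    convention (``density_universe="group_roster"``) or the connected node
    count under ``"connected_nodes"``.  Betweenness for hub detection is
    scored on the within-group induced subgraph by default, or on the full
    network (restricted to the group's members) with
    ``bc_scope="full_network"``.
    """
    cfg = config or net.provenance or AnalysisConfig()
    if roster.name != group:
        raise ValueError(f"roster {roster.name!r} does not match group {group!r}")
    sub = induced_group_subnetwork(net, group)
    if cfg.density_universe == "group_roster":
        universe = roster.size
    else:
        universe = sub.n_nodes
    density = network_density(sub.n_edges, universe) if sub.n_edges else 0.0

    if cfg.bc_scope == "within_group":
        bc = betweenness_centrality(sub, normalized=True)
    else:
        full_bc = betweenness_centrality(net, normalized=True)
        bc = {n: s for n, s in full_bc.items() if net.group_of(n) == group}
    hubs = detect_hubs(bc, cfg.hub_bc_threshold)
    return NetworkSummary(
        group=group,
        edge_count=sub.n_edges,
        density=density,
        hub_count=len(hubs),
        hub_names=tuple(hubs),
    )


# ---------------------------------------------------------------------------
# exporters


def write_graphml(
    net: BiomarkerNetwork,
    dest: Union[str, Path],
    config: AnalysisConfig | None = None,
) -> None:
    """GraphML export with node attributes group/degree/bc/is_hub and edge rho."""
    cfg = config or net.provenance or AnalysisConfig()
    g = net.graph.copy()
    for m in node_metrics(net, cfg):
        g.nodes[m.biomarker].update(
            degree=m.degree, bc=m.bc, is_hub=m.is_hub
        )
    nx.write_graphml(g, str(dest))


def write_group_summaries(
    summaries: Sequence[NetworkSummary],
    dest: Union[str, Path, TextIO],
    delimiter: str = ",",
) -> None:
    """Delimited summary table: network, edge_count, density (2 d.p.), hub_count."""
    buf = io.StringIO()
    buf.write(delimiter.join(["network", "edge_count", "density", "hub_count"]) + "\n")
    for s in summaries:
        buf.write(
            delimiter.join(
                [s.group, str(s.edge_count), f"{s.density:.2f}", str(s.hub_count)]
            )
            + "\n"
        )
    payload = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(payload, encoding="utf-8")
    else:
        dest.write(payload)


def plot_group_collapsed(
    net: BiomarkerNetwork, dest: Union[str, Path], seed: int = 0
) -> None:
    """Static plot of the group-collapsed layout (cosmetic convenience).

    Groups are drawn as clusters, node size grows with degree, and a single
    line joins any two groups with at least one cross-group edge.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    if net.n_nodes:
        deg = node_degree(net)
        groups = sorted(net.groups_present())
        # one spring layout per group cluster, clusters on a circle
        import math as _math

        pos: dict[str, tuple[float, float]] = {}
        centers = {}
        for i, grp in enumerate(groups):
            angle = 2 * _math.pi * i / len(groups)
            centers[grp] = (3 * _math.cos(angle), 3 * _math.sin(angle))
        for grp in groups:
            members = [n for n in net.nodes if net.group_of(n) == grp]
            sub = net.graph.subgraph(members)
            local = nx.spring_layout(sub, seed=seed)
            cx, cy = centers[grp]
            for n, (x, y) in local.items():
                pos[n] = (cx + x, cy + y)
        sizes = [60 + 60 * deg[n] for n in net.graph.nodes]
        nx.draw_networkx_nodes(net.graph, pos, node_size=sizes, ax=ax)
        nx.draw_networkx_edges(
            net.graph,
            pos,
            edgelist=[
                (a, b)
                for a, b, d in net.graph.edges(data=True)
                if d["within_group"]
            ],
            ax=ax,
        )
        collapsed = collapse_to_group_level(net)
        for (g1, g2), _count in collapsed.connectors.items():
            (x1, y1), (x2, y2) = centers[g1], centers[g2]
            ax.plot([x1, x2], [y1, y2], linestyle="--", color="grey")
        nx.draw_networkx_labels(net.graph, pos, font_size=6, ax=ax)
    ax.set_axis_off()
    fig.savefig(str(dest), dpi=150)
    plt.close(fig)
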