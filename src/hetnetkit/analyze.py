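"""Similarity projection and network topology reporting.

A bipartite layer of a hetnet (say phenotype-gene) can be projected onto
one side: two diseases are connected when they share at least a threshold
number of genes, the edge weight being the shared-gene count. "More than
2 shared genes" is expressed as ``min_shared=3`` — the API takes the
minimum count, never a strict-greater bound.

Topology reports cover the statistics commonly used to contrast disease
networks: node/edge counts and their N/E ratio, per-kind tallies,
connected-component sizes, the degree distribution, neighborhood
connectivity (mean neighbor degree, aggregated by degree) and the
shortest-path-length distribution of the largest component. Degree,
component and path statistics are computed on the simple undirected graph
induced by the network, with self-loops dropped; both full-network and
largest-component figures are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx

from .core import EdgeTypeError, HetNet

__all__ = [
    "SimilarityNetwork",
    "TopologyReport",
    "similarity_projection",
    "topology_report",
    "largest_component",
    "degree_opacity",
    "ne_ratio",
]


def ne_ratio(n_nodes: int, n_edges: int) -> float | None:
    """Node-to-edge ratio rounded half-up to 2 decimals; None if no edges."""
    if n_edges == 0:
        return None
    return float(
        (Decimal(n_nodes) / Decimal(n_edges)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class SimilarityNetwork:
    """Homogeneous weighted graph from a bipartite projection.

    Nodes are all nodes of the projected kind; an edge's integer weight is
    the number of shared neighbors of the via kind, present iff
    weight >= min_shared. Symmetric, no self-edges.
    """

    kind: str
    via_kind: str
    min_shared: int
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, a: str, b: str) -> int | None:
        if self.graph.has_edge(a, b):
            return self.graph.edges[a, b]["weight"]
        return None

    def to_hetnet(self, edge_kind: str | None = None) -> HetNet:
        """Represent the projection as a HetNet with a self-kind edge kind,
        so it exports through the same writers as any typed network."""
        from .core import EdgeKind, MetaGraph

        name = edge_kind or f"{self.kind}-{self.kind}"
        mg = MetaGraph(
            node_kinds=frozenset({self.kind}),
            edge_kinds={name: EdgeKind(name, self.kind, self.kind)},
        )
        net = HetNet(mg)
        for n, data in self.graph.nodes(data=True):
            net.add_node(n, self.kind, label=data.get("label", n))
        for a, b, w in self.graph.edges(data="weight"):
            net.add_edge(a, b, name, weight=int(w))
        return net


def similarity_projection(
    net: HetNet, project_kind: str, via_kind: str, min_shared: int = 1
) -> SimilarityNetwork:
    """Project a bipartite layer onto ``project_kind``.

    Edge (a, b) carries weight |N(a) ∩ N(b)| restricted to ``via_kind``
    neighbors reached through the metagraph's edge kind(s) linking the two
    kinds; kept iff weight >= min_shared.
    """
    if min_shared < 1:
        raise ValueError(f"min_shared must be >= 1, got {min_shared}")
    linking = net.metagraph.kinds_linking(project_kind, via_kind)
    if not linking:
        raise EdgeTypeError(
            f"metagraph has no edge kind linking {project_kind!r} and {via_kind!r}"
        )
    linking_names = {ek.name for ek in linking}

    sim = SimilarityNetwork(kind=project_kind, via_kind=via_kind, min_shared=min_shared)
    members = sorted(net.nodes(project_kind))
    neighbor_sets: dict[str, set[str]] = {}
    for m in members:
        sim.graph.add_node(m, label=net.graph.nodes[m].get("label", m))
        nbrs: set[str] = set()
        for ekind in linking_names:
            nbrs |= {
                n for n in net.neighbors(m, ekind)
                if net.node_kind(n) == via_kind
            }
        neighbor_sets[m] = nbrs
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            w = len(neighbor_sets[a] & neighbor_sets[b])
            if w >= min_shared:
                sim.graph.add_edge(a, b, weight=w)
    return sim


def _simple_graph(net: HetNet) -> nx.Graph:
    """Collapse the typed multigraph to a simple graph, dropping self-loops."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes(data=True))
    for u, v in net.graph.edges():
        if u != v:
            g.add_edge(u, v)
    return g


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int  # typed hetnet edges
    n_edges_simple: int  # distinct node pairs, self-loops excluded
    ne_ratio: float | None
    nodes_by_kind: dict[str, int]
    edges_by_kind: dict[str, int]
    component_sizes: list[int]  # descending
    degree_distribution: dict[int, int]
    neighborhood_connectivity: dict[int, float]
    lcc_n_nodes: int
    lcc_n_edges: int
    lcc_ne_ratio: float | None
    lcc_path_length_distribution: dict[int, int]  # hop count -> unordered pairs

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_edges_simple": self.n_edges_simple,
            "ne_ratio": self.ne_ratio,
            "nodes_by_kind": self.nodes_by_kind,
            "edges_by_kind": self.edges_by_kind,
            "component_sizes": self.component_sizes,
            "degree_distribution": {str(k): v for k, v in sorted(self.degree_distribution.items())},
            "neighborhood_connectivity": {
                str(k): v for k, v in sorted(self.neighborhood_connectivity.items())
            },
            "largest_component": {
                "n_nodes": self.lcc_n_nodes,
                "n_edges": self.lcc_n_edges,
                "ne_ratio": self.lcc_ne_ratio,
                "path_length_distribution": {
                    str(k): v for k, v in sorted(self.lcc_path_length_distribution.items())
                },
            },
        }


def topology_report(net: HetNet, include_paths: bool = True) -> TopologyReport:
    """Compute the report; ``include_paths=False`` skips the all-pairs
    shortest-path distribution (quadratic in the largest component)."""
    counts = net.counts()
    g = _simple_graph(net)

    components = sorted((len(c) for c in nx.connected_components(g)), reverse=True)

    degree_distribution: dict[int, int] = {}
    for _, d in g.degree():
        degree_distribution[d] = degree_distribution.get(d, 0) + 1

    # neighborhood connectivity: mean over nodes of degree d of their mean
    # neighbor degree (the statistic reported per degree in topology panels)
    nbr_deg = nx.average_neighbor_degree(g)
    by_degree: dict[int, list[float]] = {}
    for n, d in g.degree():
        if d > 0:
            by_degree.setdefault(d, []).append(nbr_deg[n])
    neighborhood_connectivity = {
        d: sum(vals) / len(vals) for d, vals in by_degree.items()
    }

    if g.number_of_nodes():
        lcc_nodes = _largest_component_nodes(g)
        lcc = g.subgraph(lcc_nodes)
        path_dist: dict[int, int] = {}
        if include_paths:
            for src, lengths in nx.all_pairs_shortest_path_length(lcc):
                for dst, hops in lengths.items():
                    if src < dst:  # unordered pairs once
                        path_dist[hops] = path_dist.get(hops, 0) + 1
        lcc_n, lcc_e = lcc.number_of_nodes(), lcc.number_of_edges()
    else:
        path_dist = {}
        lcc_n = lcc_e = 0

    return TopologyReport(
        n_nodes=counts["n_nodes"],
        n_edges=counts["n_edges"],
        n_edges_simple=g.number_of_edges(),
        ne_ratio=ne_ratio(counts["n_nodes"], counts["n_edges"]),
        nodes_by_kind=counts["nodes"],
        edges_by_kind=counts["edges"],
        component_sizes=components,
        degree_distribution=degree_distribution,
        neighborhood_connectivity=neighborhood_connectivity,
        lcc_n_nodes=lcc_n,
        lcc_n_edges=lcc_e,
        lcc_ne_ratio=ne_ratio(lcc_n, lcc_e),
        lcc_path_length_distribution=path_dist,
    )


def _largest_component_nodes(g: nx.Graph) -> set[str]:
    """Largest component; ties broken by smallest lexicographic member id."""
    comps = list(nx.connected_components(g))
    if not comps:
        return set()
    max_size = max(len(c) for c in comps)
    return min((c for c in comps if len(c) == max_size), key=min)


def largest_component(net: HetNet) -> HetNet:
    """Induced subnetwork on the largest connected node set (empty in, empty out)."""
    if net.n_nodes == 0:
        return net.copy()
    g = _simple_graph(net)
    return net.subnetwork(_largest_component_nodes(g))


def degree_opacity(net: HetNet, kind: str) -> dict[str, float]:
    """Degree of each node of ``kind`` scaled to [0, 1] by the kind's max.

    The highest-degree node gets 1.0; isolated nodes get 0.0; empty kind
    gives an empty map. Degrees are simple-graph degrees (self-loops and
    parallel typed edges collapsed).
    """
    g = _simple_graph(net)
    members = sorted(net.nodes(kind))
    if not members:
        return {}
    degrees = {m: g.degree(m) for m in members}
    peak = max(degrees.values())
    if peak == 0:
        return {m: 0.0 for m in members}
    return {m: d / peak for m, d in degrees.items()}
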