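"""Seed-and-expand hetnet construction.

Networks are built from a starting node type — a disease, gene or drug —
in two expansion tiers. Tier 1 attaches, for each requested edge kind,
every edge incident to the seed set together with its opposite endpoint
(e.g. from diseases, add their genes, drugs and tissues directly). Tier 2
repeats the same incidence expansion from the tier-1 node set (e.g. add
miRNAs, side effects and first-degree protein interactions). Within a
tier every edge kind is evaluated against the node set at the start of
that tier, so the order in which kinds are listed does not matter.

After both tiers, a closure pass adds any remaining edge of a requested
kind whose two endpoints are both already in the network (default on).
This is what makes, for instance, protein interactions among tier-2-added
genes appear, yielding an interconnected interactome rather than a star.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import HetNet, MetaGraph, MissingNodeError, default_metagraph

__all__ = ["ResourceStore", "BuildRequest", "build", "subnetwork_by_min_disease_degree"]

SEED_KINDS = ("phenotype", "gene", "drug")


@dataclass
class ResourceStore:
    """Post-filter, post-idmap edge tables and node registries, in memory.

    ``nodes`` maps node kind → {node id → label}; ``edges`` maps edge kind
    name → list of (source_id, target_id, attrs) with source of the edge
    kind's first endpoint kind.
    """

    metagraph: MetaGraph = field(default_factory=default_metagraph)
    nodes: dict[str, dict[str, str]] = field(default_factory=dict)
    edges: dict[str, list[tuple[str, str, dict]]] = field(default_factory=dict)

    def register_node(self, kind: str, node_id: str, label: str | None = None) -> None:
        if kind not in self.metagraph.node_kinds:
            raise ValueError(f"unknown node kind {kind!r}")
        self.nodes.setdefault(kind, {}).setdefault(node_id, label or node_id)

    def add_edge(self, kind: str, source: str, target: str, **attrs) -> None:
        ek = self.metagraph.edge_kind(kind)
        # auto-register endpoints under the edge kind's endpoint kinds
        self.register_node(ek.endpoint_a, source)
        self.register_node(ek.endpoint_b, target)
        self.edges.setdefault(kind, []).append((source, target, attrs))

    def node_kind_of(self, node_id: str) -> str | None:
        for kind, reg in self.nodes.items():
            if node_id in reg:
                return kind
        return None

    def full_network(self) -> HetNet:
        """Materialize everything in the store as one HetNet."""
        net = HetNet(self.metagraph)
        for kind in sorted(self.nodes):
            for nid in sorted(self.nodes[kind]):
                net.add_node(nid, kind, label=self.nodes[kind][nid])
        for ekind in sorted(self.edges):
            for s, t, attrs in self.edges[ekind]:
                net.add_edge(s, t, ekind, **attrs)
        return net


@dataclass(frozen=True)
class BuildRequest:
    """What to build: seeds plus the edge kinds of each expansion tier."""

    seed_kind: str
    seed_ids: frozenset[str]
    tier1: frozenset[str] = frozenset()
    tier2: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.seed_kind not in SEED_KINDS:
            raise ValueError(
                f"seed kind must be one of {SEED_KINDS}, got {self.seed_kind!r}"
            )

    @classmethod
    def make(cls, seed_kind: str, seed_ids: Iterable[str],
             tier1: Iterable[str] = (), tier2: Iterable[str] = ()) -> "BuildRequest":
        return cls(seed_kind, frozenset(seed_ids), frozenset(tier1), frozenset(tier2))


def _expand_tier(net: HetNet, store: ResourceStore, edge_kinds: frozenset[str]) -> None:
    """Add edges of the given kinds incident to net's current nodes, plus
    their opposite endpoints. All kinds see the same starting node set."""
    frontier = set(net.nodes())
    additions: list[tuple[str, str, str, str, str, dict]] = []
    for ekind in sorted(edge_kinds):
        ek = net.metagraph.edge_kind(ekind)
        for s, t, attrs in store.edges.get(ekind, ()):
            if s in frontier or t in frontier:
                additions.append((ekind, ek.endpoint_a, s, ek.endpoint_b, t, attrs))
    for ekind, ka, s, kb, t, attrs in additions:
        if s not in net:
            net.add_node(s, ka, label=store.nodes.get(ka, {}).get(s, s))
        if t not in net:
            net.add_node(t, kb, label=store.nodes.get(kb, {}).get(t, t))
        net.add_edge(s, t, ekind, **attrs)


def _close_edges(net: HetNet, store: ResourceStore, edge_kinds: frozenset[str]) -> None:
    """Add edges of requested kinds whose endpoints are both already present."""
    present = set(net.nodes())
    for ekind in sorted(edge_kinds):
        for s, t, attrs in store.edges.get(ekind, ()):
            if s in present and t in present:
                net.add_edge(s, t, ekind, **attrs)


def build(store: ResourceStore, req: BuildRequest, close_within: bool = True) -> HetNet:
    """Seed-and-expand construction.

    Seeds are always included (with no incident edges they stay isolated).
    ``close_within`` controls the final closure pass over both tiers' edge
    kinds. Unknown seed ids raise; a requested edge kind touching no node
    kind in the network is simply inert. Deterministic for a given store
    and request.
    """
    for ekind in sorted(req.tier1 | req.tier2):
        store.metagraph.edge_kind(ekind)  # raises on unknown kinds
    registry = store.nodes.get(req.seed_kind, {})
    missing = sorted(s for s in req.seed_ids if s not in registry)
    if missing:
        raise MissingNodeError(f"seed ids not in store: {missing}")

    net = HetNet(store.metagraph)
    for sid in sorted(req.seed_ids):
        net.add_node(sid, req.seed_kind, label=registry[sid])
    _expand_tier(net, store, req.tier1)
    _expand_tier(net, store, req.tier2)
    if close_within:
        _close_edges(net, store, req.tier1 | req.tier2)
    return net


def subnetwork_by_min_disease_degree(net: HetNet, k: int) -> HetNet:
    """Restrict to genes associated with at least ``k`` distinct phenotypes.

    Keeps every gene with >= k distinct phenotype neighbors (via
    phenotype-gene edges), the phenotype nodes those genes link to, and
    all edges among kept nodes — including protein interactions between
    kept genes. With k=1 this is the identity on disease-linked genes.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    kept_genes = {
        g for g in net.nodes("gene")
        if len(net.neighbors(g, "phenotype-gene")) >= k
    }
    kept_phenotypes: set[str] = set()
    for g in kept_genes:
        kept_phenotypes |= net.neighbors(g, "phenotype-gene")
    return net.subnetwork(kept_genes | kept_phenotypes)
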