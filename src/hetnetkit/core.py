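"""Typed heterogeneous network (hetnet) data model.

A hetnet is a graph whose nodes and edges carry semantic types. The schema
level is a *metagraph*: its nodes are entity kinds (phenotype, gene, ...)
and its edges are the permitted interaction kinds (phenotype-gene,
gene-gene, ...). Instance networks type-check against the metagraph on
every insertion.

The default metagraph covers six entity kinds and nine interaction kinds
spanning disease genetics (phenotype-gene), physiopathology
(phenotype-tissue), expression (gene-tissue), pharmacology (drug-phenotype,
drug-gene, drug-side_effect, side_effect-tissue), the protein interactome
(gene-gene) and post-transcriptional regulation (mirna-gene). The metagraph
is cyclic by design; no acyclicity is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "NODE_KINDS",
    "EdgeKind",
    "MetaGraph",
    "HetNet",
    "HetNetError",
    "MissingNodeError",
    "EdgeTypeError",
    "default_metagraph",
]

#: The six entity kinds of the default metagraph.
NODE_KINDS = ("phenotype", "gene", "mirna", "tissue", "drug", "side_effect")


class HetNetError(ValueError):
    """Base class for hetnet construction errors."""


class MissingNodeError(HetNetError):
    """An edge referenced a node id absent from the network."""


class EdgeTypeError(HetNetError):
    """An edge violated the metagraph's typing rules."""


@dataclass(frozen=True)
class EdgeKind:
    """A permitted interaction kind between two (possibly equal) node kinds."""

    name: str
    endpoint_a: str
    endpoint_b: str

    def endpoint_kinds(self) -> frozenset[str]:
        return frozenset({self.endpoint_a, self.endpoint_b})

    def matches(self, kind_a: str, kind_b: str) -> bool:
        """True if the unordered kind pair fits this edge kind."""
        return {kind_a, kind_b} == {self.endpoint_a, self.endpoint_b}


@dataclass(frozen=True)
class MetaGraph:
    """Schema graph: registered node kinds and permitted edge kinds."""

    node_kinds: frozenset[str]
    edge_kinds: Mapping[str, EdgeKind] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ek in self.edge_kinds.values():
            if ek.endpoint_a not in self.node_kinds or ek.endpoint_b not in self.node_kinds:
                raise EdgeTypeError(
                    f"edge kind {ek.name!r} references unregistered node kind"
                )

    def edge_kind(self, name: str) -> EdgeKind:
        try:
            return self.edge_kinds[name]
        except KeyError:
            raise EdgeTypeError(f"unknown edge kind {name!r}") from None

    def has_edge_kind(self, name: str) -> bool:
        return name in self.edge_kinds

    def kinds_linking(self, kind_a: str, kind_b: str) -> list[EdgeKind]:
        """All edge kinds whose endpoints are the unordered pair (kind_a, kind_b)."""
        return [ek for ek in self.edge_kinds.values() if ek.matches(kind_a, kind_b)]


_DEFAULT_EDGE_KINDS = (
    ("phenotype-gene", "phenotype", "gene"),
    ("phenotype-tissue", "phenotype", "tissue"),
    ("gene-tissue", "gene", "tissue"),
    ("drug-phenotype", "drug", "phenotype"),
    ("drug-gene", "drug", "gene"),
    ("drug-side_effect", "drug", "side_effect"),
    ("side_effect-tissue", "side_effect", "tissue"),
    ("gene-gene", "gene", "gene"),
    ("mirna-gene", "mirna", "gene"),
)


def default_metagraph() -> MetaGraph:
    """The six-node-kind, nine-edge-kind metagraph used throughout."""
    return MetaGraph(
        node_kinds=frozenset(NODE_KINDS),
        edge_kinds={
            name: EdgeKind(name, a, b) for name, a, b in _DEFAULT_EDGE_KINDS
        },
    )


class HetNet:
    """An instance-level typed network constrained by a metagraph.

    Backed by a :class:`networkx.MultiGraph` whose edge keys are edge-kind
    names, so at most one edge of a given kind exists between a node pair
    (distinct kinds between the same pair are distinct edges). All edges
    are undirected. Node attributes always include ``kind`` and ``label``.
    """

    def __init__(self, metagraph: MetaGraph | None = None) -> None:
        self.metagraph = metagraph if metagraph is not None else default_metagraph()
        self.graph = nx.MultiGraph()

    # -- nodes ---------------------------------------------------------

    def add_node(self, node_id: str, kind: str, label: str | None = None, **attrs) -> None:
        if not node_id:
            raise HetNetError("node id must be non-empty")
        if "\t" in node_id:
            raise HetNetError(f"node id may not contain tabs: {node_id!r}")
        if kind not in self.metagraph.node_kinds:
            raise EdgeTypeError(f"unknown node kind {kind!r}")
        if node_id in self.graph:
            existing = self.graph.nodes[node_id]["kind"]
            if existing != kind:
                raise EdgeTypeError(
                    f"node {node_id!r} already present with kind {existing!r}, "
                    f"cannot re-add as {kind!r}"
                )
            self.graph.nodes[node_id].update(attrs)
            if label is not None:
                self.graph.nodes[node_id]["label"] = label
        else:
            self.graph.add_node(
                node_id, kind=kind, label=label if label is not None else node_id, **attrs
            )

    def has_node(self, node_id: str) -> bool:
        return node_id in self.graph

    def node_kind(self, node_id: str) -> str:
        try:
            return self.graph.nodes[node_id]["kind"]
        except KeyError:
            raise MissingNodeError(f"no such node: {node_id!r}") from None

    def nodes(self, kind: str | None = None) -> Iterator[str]:
        if kind is None:
            yield from self.graph.nodes
        else:
            for n, k in self.graph.nodes(data="kind"):
                if k == kind:
                    yield n

    # -- edges ---------------------------------------------------------

    def add_edge(self, source: str, target: str, kind: str, **attrs) -> None:
        """Insert an undirected typed edge.

        The canonical key is (min(id), max(id), kind); re-adding an existing
        edge merges attributes (later value wins per key) without creating a
        duplicate.
        """
        ek = self.metagraph.edge_kind(kind)
        for nid in (source, target):
            if nid not in self.graph:
                raise MissingNodeError(f"edge endpoint not in network: {nid!r}")
        ka, kb = self.graph.nodes[source]["kind"], self.graph.nodes[target]["kind"]
        if not ek.matches(ka, kb):
            raise EdgeTypeError(
                f"edge kind {kind!r} links {ek.endpoint_a}-{ek.endpoint_b}, "
                f"got {ka}-{kb} ({source!r}, {target!r})"
            )
        u, v = (source, target) if source <= target else (target, source)
        if self.graph.has_edge(u, v, key=kind):
            self.graph.edges[u, v, kind].update(attrs)
        else:
            self.graph.add_edge(u, v, key=kind, kind=kind, **attrs)

    def has_edge(self, source: str, target: str, kind: str) -> bool:
        return self.graph.has_edge(source, target, key=kind)

    def edges(self, kind: str | None = None) -> Iterator[tuple[str, str, str, dict]]:
        """Yield (source, target, kind, attrs) with source <= target."""
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            if kind is not None and k != kind:
                continue
            a, b = (u, v) if u <= v else (v, u)
            yield a, b, k, {kk: vv for kk, vv in d.items() if kk != "kind"}

    def neighbors(self, node_id: str, edge_kind: str | None = None) -> set[str]:
        if node_id not in self.graph:
            raise MissingNodeError(f"no such node: {node_id!r}")
        if edge_kind is None:
            return set(self.graph[node_id])
        out: set[str] = set()
        for nbr, keyed in self.graph[node_id].items():
            if edge_kind in keyed:
                out.add(nbr)
        return out

    # -- summaries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def counts(self) -> dict:
        """Per-kind node and edge tallies plus totals."""
        node_counts = {k: 0 for k in sorted(self.metagraph.node_kinds)}
        for _, k in self.graph.nodes(data="kind"):
            node_counts[k] += 1
        edge_counts = {k: 0 for k in sorted(self.metagraph.edge_kinds)}
        for _, _, k in self.graph.edges(keys=True):
            edge_counts[k] += 1
        return {
            "nodes": node_counts,
            "edges": edge_counts,
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
        }

    def copy(self) -> "HetNet":
        out = HetNet(self.metagraph)
        out.graph = self.graph.copy()
        return out

    def subnetwork(self, node_ids: Iterable[str]) -> "HetNet":
        """Induced subnetwork on the given node ids (edges among them kept)."""
        keep = set(node_ids)
        out = HetNet(self.metagraph)
        out.graph = self.graph.subgraph(keep).copy()
        return out

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    def __repr__(self) -> str:
        return f"HetNet(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
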