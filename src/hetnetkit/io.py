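"""Network import/export: SIF, GraphML and TSV node/edge tables.

All writers emit deterministically ordered output (sorted ids) so exports
are diffable. The SIF dialect is tab-delimited — one
``source<TAB>edge_kind<TAB>target`` line per edge, isolated nodes as bare
ids — with node kinds and labels in a sidecar TSV, since SIF itself
carries no attributes. GraphML keeps node attributes (kind, label, extras)
and edge attributes (kind, weight, extras) with types intact, so
write/read round-trips preserve the typed node and edge multisets exactly.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .core import HetNet, MetaGraph, default_metagraph

__all__ = [
    "write_sif",
    "read_sif",
    "write_graphml",
    "read_graphml",
    "write_node_table",
    "write_edge_table",
    "sidecar_path",
    "FormatError",
]

_SCALARS = (str, int, float, bool)


class FormatError(ValueError):
    """An attribute value cannot be serialized to the requested format."""


def sidecar_path(sif_path) -> Path:
    """Node-attribute TSV path accompanying a SIF file."""
    p = Path(sif_path)
    return p.with_suffix(p.suffix + ".nodes.tsv") if p.suffix != ".sif" \
        else p.with_suffix(".nodes.tsv")


def _sorted_edges(net: HetNet):
    return sorted((u, k, v, d) for u, v, k, d in net.edges())


def write_sif(net: HetNet, path, nodes_path=None) -> tuple[Path, Path]:
    """Write SIF + node sidecar; returns (sif_path, nodes_path)."""
    path = Path(path)
    nodes_path = Path(nodes_path) if nodes_path is not None else sidecar_path(path)
    connected: set[str] = set()
    lines = []
    for u, k, v, _ in _sorted_edges(net):
        lines.append(f"{u}\t{k}\t{v}")
        connected.update((u, v))
    for n in sorted(set(net.nodes()) - connected):
        lines.append(n)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    write_node_table(net, nodes_path)
    return path, nodes_path


def read_sif(path, nodes_path=None, metagraph: MetaGraph | None = None) -> HetNet:
    """Read a SIF file with its node sidecar back into a HetNet."""
    path = Path(path)
    nodes_path = Path(nodes_path) if nodes_path is not None else sidecar_path(path)
    net = HetNet(metagraph if metagraph is not None else default_metagraph())
    nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)
    attr_cols = [c for c in nodes.columns if c not in ("id", "kind", "label")]
    for row in nodes.itertuples():
        extras = {
            c: getattr(row, c) for c in attr_cols
            if pd.notna(getattr(row, c))
        }
        net.add_node(row.id, row.kind, label=row.label, **extras)
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            continue  # isolated node, already present via sidecar
        if len(parts) != 3:
            raise FormatError(f"bad SIF line: {line!r}")
        u, k, v = parts
        net.add_edge(u, v, k)
    return net


def write_node_table(net: HetNet, path) -> Path:
    path = Path(path)
    rows = []
    for n in sorted(net.nodes()):
        data = dict(net.graph.nodes[n])
        rows.append({"id": n, "kind": data.pop("kind"), "label": data.pop("label"), **data})
    pd.DataFrame(rows, columns=_stable_columns(rows, ("id", "kind", "label"))).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_edge_table(net: HetNet, path) -> Path:
    path = Path(path)
    rows = []
    for u, k, v, d in _sorted_edges(net):
        extras = {kk: vv for kk, vv in d.items() if kk != "kind"}
        rows.append({"source": u, "target": v, "kind": k, **extras})
    pd.DataFrame(rows, columns=_stable_columns(rows, ("source", "target", "kind"))).to_csv(
        path, sep="\t", index=False
    )
    return path


def _stable_columns(rows: list[dict], first: tuple[str, ...]) -> list[str]:
    cols = list(first)
    for r in rows:
        for c in r:
            if c not in cols:
                cols.append(c)
    return cols


def _check_serializable(attrs: dict, where: str) -> None:
    for k, v in attrs.items():
        if not isinstance(v, _SCALARS):
            raise FormatError(
                f"attribute {k!r} on {where} has non-serializable value {v!r}"
            )


def write_graphml(net: HetNet, path) -> Path:
    """Write GraphML with undirected edgedefault; attribute types preserved."""
    path = Path(path)
    out = nx.MultiGraph()
    for n in sorted(net.nodes()):
        attrs = dict(net.graph.nodes[n])
        _check_serializable(attrs, f"node {n!r}")
        out.add_node(n, **attrs)
    for u, k, v, d in _sorted_edges(net):
        attrs = {"kind": k, **d}
        _check_serializable(attrs, f"edge ({u!r}, {v!r}, {k!r})")
        out.add_edge(u, v, key=k, **attrs)
    nx.write_graphml(out, path, edge_id_from_attribute="kind")
    return path


def read_graphml(path, metagraph: MetaGraph | None = None) -> HetNet:
    g = nx.read_graphml(path, force_multigraph=True)
    net = HetNet(metagraph if metagraph is not None else default_metagraph())
    for n, data in sorted(g.nodes(data=True)):
        attrs = dict(data)
        kind = attrs.pop("kind")
        label = attrs.pop("label", n)
        net.add_node(n, kind, label=label, **attrs)
    for u, v, d in g.edges(data=True):
        attrs = dict(d)
        kind = attrs.pop("kind")
        net.add_edge(u, v, kind, **attrs)
    return net
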