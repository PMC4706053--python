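"""OBO ontologies: parsing, rooting, DAG queries and annotation propagation.

Disease, tissue and side-effect vocabularies are rooted DAGs of terms
related by ``is_a``. Two operations here mirror how tissue annotations are
attached to phenotype and side-effect hierarchies in practice:

* ``root_at`` restricts an ontology to one subtree — e.g. restricting the
  BRENDA tissue ontology to 'whole body' (BTO:0001489) discards the
  non-animal branches.
* ``propagate_annotations`` takes a small manual map from high-level terms
  to tissue terms and pushes it down ``is_a`` chains, so every descendant
  of an annotated term inherits the union of its ancestors' tissues
  ("ontology inference"). Propagation is downward only and follows is_a
  exclusively; part_of and other relations are ignored.

Parsing is delegated to :mod:`obonet`; this module adds the validation the
pipeline needs (dangling is_a targets, is_a cycles) and excludes obsolete
terms from query results.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import obonet

__all__ = [
    "OntologyTerm",
    "Ontology",
    "OboParseError",
    "OntologyLookupError",
    "parse_obo",
    "propagate_annotations",
]


class OboParseError(ValueError):
    """Malformed OBO input (dangling is_a target, is_a cycle, ...)."""


class OntologyLookupError(KeyError):
    """A queried term id is not in the ontology."""


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str
    parents: frozenset[str] = frozenset()
    xrefs: frozenset[str] = frozenset()
    obsolete: bool = False


@dataclass
class Ontology:
    """A set of terms whose is_a links form a DAG."""

    terms: dict[str, OntologyTerm]
    root: str | None = None
    _child_to_parent: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise OboParseError(
                        f"term {t.id!r} has is_a target {p!r} not defined in the ontology"
                    )
                g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OboParseError(f"is_a cycle detected: {' -> '.join(u for u, _ in cyc)}")
        self._child_to_parent = g

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise OntologyLookupError(f"no such term: {term_id!r}")

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` by is_a chains (exclusive)."""
        self._require(term_id)
        return nx.descendants(self._child_to_parent, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """All terms from which ``term_id`` is reachable by is_a chains (exclusive)."""
        self._require(term_id)
        return nx.ancestors(self._child_to_parent, term_id)

    def root_at(self, root_id: str) -> "Ontology":
        """Restrict to ``root_id`` and its descendants, pruning dangling parent links."""
        self._require(root_id)
        keep = self.descendants(root_id) | {root_id}
        terms = {
            tid: OntologyTerm(
                id=t.id,
                name=t.name,
                parents=t.parents & keep,
                xrefs=t.xrefs,
                obsolete=t.obsolete,
            )
            for tid, t in self.terms.items()
            if tid in keep
        }
        return Ontology(terms=terms, root=root_id)

    def non_obsolete_ids(self) -> set[str]:
        return {tid for tid, t in self.terms.items() if not t.obsolete}

    def xref_pairs(self) -> list[tuple[str, str]]:
        """(term_id, xref) pairs over all non-obsolete terms, sorted."""
        return sorted(
            (tid, x)
            for tid, t in self.terms.items()
            if not t.obsolete
            for x in t.xrefs
        )


def parse_obo(source) -> Ontology:
    """Parse OBO 1.2 text (path, file handle or string) into an Ontology.

    Recognized tags: id, name, is_a, xref, is_obsolete; anything else is
    ignored. A term whose is_a points outside the file, or an is_a cycle,
    raises :class:`OboParseError`.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    graph = obonet.read_obo(source, ignore_obsolete=False)
    terms: dict[str, OntologyTerm] = {}
    for tid, data in graph.nodes(data=True):
        if not data:
            # obonet materializes is_a targets that lack their own [Term]
            # stanza as bare nodes; treat as a dangling reference.
            offenders = sorted(
                u for u, v, k in graph.edges(keys=True) if v == tid and k == "is_a"
            )
            raise OboParseError(
                f"term(s) {offenders} have is_a target {tid!r} "
                "not defined in the ontology"
            )
        parents = frozenset(
            v for _, v, k in graph.out_edges(tid, keys=True) if k == "is_a"
        )
        terms[tid] = OntologyTerm(
            id=tid,
            name=data.get("name", tid),
            parents=parents,
            xrefs=frozenset(data.get("xref", ())),
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
        )
    return Ontology(terms=terms)


def propagate_annotations(
    ont: Ontology, manual: dict[str, set[str]]
) -> dict[str, frozenset[str]]:
    """Push manual term→tissue annotations down to more specific terms.

    Every non-obsolete term ``t`` maps to the union of the manual
    annotations over ``{t} ∪ ancestors(t)``; terms with an empty union are
    absent from the result. Manual entries are preserved verbatim (multiple
    annotations on one term are unioned, never overwritten).

    Raises :class:`OntologyLookupError` listing any manual keys absent from
    the ontology.
    """
    unknown = sorted(k for k in manual if k not in ont.terms)
    if unknown:
        raise OntologyLookupError(f"manual annotation keys not in ontology: {unknown}")
    result: dict[str, frozenset[str]] = {}
    for tid, term in ont.terms.items():
        if term.obsolete:
            continue
        tissues: set[str] = set()
        for source in {tid} | ont.ancestors(tid):
            tissues |= set(manual.get(source, ()))
        if tissues:
            result[tid] = frozenset(tissues)
    return result
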