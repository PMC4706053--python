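"""Identifier resolution: gene symbols to HGNC integers, phenotype xrefs to DO.

Gene nodes are keyed by the integer portion of their HGNC id, so every
resource's gene column must be pushed through an alias table that knows
current symbols, outdated symbols and synonyms. Phenotype nodes are keyed
by Disease Ontology (DO) ids where a cross-reference exists; OMIM/MeSH/EFO
ids without a DO xref pass through namespaced, so unmapped terms remain
distinct nodes rather than being silently merged.

Resolution outcomes are values, never guesses: an alias shared by several
genes, or a source id cross-referenced to several DO terms, is reported as
ambiguous with all candidates listed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "parse_hgnc_id",
    "AliasRecord",
    "AliasTable",
    "Resolution",
    "XrefMap",
    "IdFormatError",
    "AmbiguousXrefError",
]

_HGNC_RE = re.compile(r"^(?:HGNC:)?(\d+)$")

ALIAS_STATUSES = ("current", "outdated", "synonym")
PHENOTYPE_VOCABS = ("DO", "OMIM", "MeSH", "EFO")

_VOCAB_PREFIX = {"DO": "DOID", "OMIM": "OMIM", "MeSH": "MESH", "EFO": "EFO"}


class IdFormatError(ValueError):
    """Malformed identifier or unknown vocabulary label."""


class AmbiguousXrefError(ValueError):
    """One source id cross-references multiple canonical terms."""


def parse_hgnc_id(raw: str) -> int:
    """Extract the integer portion of an HGNC id ('HGNC:5' or '5' -> 5)."""
    m = _HGNC_RE.match(str(raw).strip())
    if not m:
        raise IdFormatError(f"not an HGNC id: {raw!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class AliasRecord:
    symbol: str
    hgnc_id: int
    status: str  # current | outdated | synonym

    def __post_init__(self) -> None:
        if not self.symbol:
            raise IdFormatError("alias symbol must be non-empty")
        if self.hgnc_id <= 0:
            raise IdFormatError(f"hgnc_id must be positive, got {self.hgnc_id}")
        if self.status not in ALIAS_STATUSES:
            raise IdFormatError(f"unknown alias status {self.status!r}")


@dataclass(frozen=True)
class Resolution:
    """Outcome of a symbol/id lookup: found, not_found or ambiguous."""

    status: str
    hgnc_id: int | None = None
    candidates: tuple[int, ...] = ()

    @property
    def found(self) -> bool:
        return self.status == "found"


class AliasTable:
    """Symbol → HGNC resolution with documented precedence.

    Current symbols resolve first; otherwise a unique alias (outdated
    symbol or synonym) resolves; an alias pointing at several genes is an
    explicit ambiguity. Matching is case-sensitive exact match by default
    (HGNC symbols are case-significant); ``case_insensitive=True`` enables
    a fallback on the lowercased symbol.
    """

    def __init__(self, records: Iterable[AliasRecord]) -> None:
        self.records = tuple(records)
        self.current_index: dict[str, int] = {}
        self.alias_index: dict[str, set[int]] = {}
        for r in self.records:
            if r.status == "current":
                prev = self.current_index.get(r.symbol)
                if prev is not None and prev != r.hgnc_id:
                    raise IdFormatError(
                        f"current symbol {r.symbol!r} claimed by HGNC "
                        f"{prev} and {r.hgnc_id}"
                    )
                self.current_index[r.symbol] = r.hgnc_id
            else:
                self.alias_index.setdefault(r.symbol, set()).add(r.hgnc_id)

    @classmethod
    def from_tsv(cls, path) -> "AliasTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"symbol", "hgnc_id", "status"} - set(df.columns)
        if missing:
            raise IdFormatError(f"alias table missing columns: {sorted(missing)}")
        return cls(
            AliasRecord(row.symbol, parse_hgnc_id(row.hgnc_id), row.status)
            for row in df.itertuples()
        )

    def resolve(self, query, case_insensitive: bool = False) -> Resolution:
        symbol = str(query)
        hit = self._resolve_exact(symbol)
        if hit.status == "not_found" and case_insensitive:
            folded = symbol.casefold()
            current = {
                hid for sym, hid in self.current_index.items() if sym.casefold() == folded
            }
            if len(current) == 1:
                return Resolution("found", hgnc_id=next(iter(current)))
            if len(current) > 1:
                return Resolution("ambiguous", candidates=tuple(sorted(current)))
            aliases: set[int] = set()
            for sym, hids in self.alias_index.items():
                if sym.casefold() == folded:
                    aliases |= hids
            if len(aliases) == 1:
                return Resolution("found", hgnc_id=next(iter(aliases)))
            if len(aliases) > 1:
                return Resolution("ambiguous", candidates=tuple(sorted(aliases)))
        return hit

    def _resolve_exact(self, symbol: str) -> Resolution:
        if symbol in self.current_index:
            return Resolution("found", hgnc_id=self.current_index[symbol])
        hids = self.alias_index.get(symbol, set())
        if len(hids) == 1:
            return Resolution("found", hgnc_id=next(iter(hids)))
        if len(hids) > 1:
            return Resolution("ambiguous", candidates=tuple(sorted(hids)))
        return Resolution("not_found")


def resolve_gene(table: AliasTable, query: str, case_insensitive: bool = False) -> Resolution:
    """Functional wrapper over :meth:`AliasTable.resolve`."""
    return table.resolve(query, case_insensitive=case_insensitive)


class XrefMap:
    """(vocab, source_id) → canonical phenotype id via DO cross-references."""

    def __init__(self, entries: Iterable[tuple[str, str, str]]) -> None:
        self.entries: dict[tuple[str, str], set[str]] = {}
        for vocab, source_id, do_id in entries:
            if vocab not in PHENOTYPE_VOCABS:
                raise IdFormatError(f"unknown phenotype vocabulary {vocab!r}")
            self.entries.setdefault((vocab, str(source_id)), set()).add(str(do_id))

    @classmethod
    def from_tsv(cls, path) -> "XrefMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"vocab", "source_id", "do_id"} - set(df.columns)
        if missing:
            raise IdFormatError(f"xref table missing columns: {sorted(missing)}")
        return cls((row.vocab, row.source_id, row.do_id) for row in df.itertuples())

    def lookup(self, vocab: str, source_id: str) -> tuple[str, ...]:
        """All canonical candidates for a source id (may be empty)."""
        if vocab not in PHENOTYPE_VOCABS:
            raise IdFormatError(f"unknown phenotype vocabulary {vocab!r}")
        return tuple(sorted(self.entries.get((vocab, str(source_id)), ())))

    def map_phenotype(self, vocab: str, source_id: str) -> str:
        """Canonical phenotype id: the DO xref if unique, else a namespaced
        passthrough of the source id. Multiple DO candidates raise
        :class:`AmbiguousXrefError` rather than picking one."""
        candidates = self.lookup(vocab, source_id)
        if len(candidates) > 1:
            raise AmbiguousXrefError(
                f"{vocab}:{source_id} cross-references multiple terms: {list(candidates)}"
            )
        if candidates:
            return candidates[0]
        sid = str(source_id)
        prefix = _VOCAB_PREFIX[vocab]
        if ":" in sid:
            return sid
        return f"{prefix}:{sid}"


def map_phenotype(xm: XrefMap, vocab: str, source_id: str) -> str:
    """Functional wrapper over :meth:`XrefMap.map_phenotype`."""
    return xm.map_phenotype(vocab, source_id)
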