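"""Resource table readers, inclusion filters and GWAS locus merging.

Each upstream resource arrives as a TSV edge table. Two filters implement
the stated inclusion rules:

* CTD disease-gene rows are kept only with direct "marker/mechanism"
  evidence (curated marker or mechanistic involvement, as opposed to
  therapeutic relationships).
* GWAS rows are kept at a genome-wide significance threshold, default
  p <= 1e-7 (inclusive: boundary hits count).

GWAS associations are reported per SNP locus; to get one association per
disease and region, overlapping loci of the same disease and chromosome
are unioned into maximal merged intervals and the author-reported gene of
the most significant (lowest-p) constituent becomes the primary gene.
Coordinates are 0-based half-open; "overlapping" is strict (abutting
intervals sharing zero bases do not merge). This is plain interval union,
applied to GWAS rows only — OMIM and CTD rows bypass it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GwasLocus",
    "MergedLocus",
    "SchemaError",
    "CTD_DIRECT_EVIDENCE",
    "GWAS_P_THRESHOLD",
    "read_edge_table",
    "filter_ctd_direct",
    "filter_gwas_pvalue",
    "merge_loci",
    "loci_from_table",
]

CTD_DIRECT_EVIDENCE = "marker/mechanism"
GWAS_P_THRESHOLD = 1e-7

#: Required columns per resource table.
RESOURCE_SCHEMAS = {
    "gwas": ("disease_id", "chrom", "start", "end", "reported_gene", "p_value"),
    "ctd_dg": ("disease_id", "gene", "evidence"),
    "omim": ("disease_id", "gene"),
    "drug_gene": ("drug_id", "gene"),
    "drug_disease": ("drug_id", "disease_id"),
    "drug_side_effect": ("drug_id", "se_id", "frequency"),
    "gene_tissue": ("gene", "tissue_id", "expression"),
    "mirna_gene": ("mirna_id", "gene"),
    "ppi": ("gene_a", "gene_b"),
}


class SchemaError(ValueError):
    """A resource table is missing required columns or has bad values."""


def read_edge_table(path, resource: str) -> pd.DataFrame:
    """Read a resource TSV and validate its schema."""
    if resource not in RESOURCE_SCHEMAS:
        raise SchemaError(f"unknown resource {resource!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(RESOURCE_SCHEMAS[resource]) - set(df.columns)
    if missing:
        raise SchemaError(f"{resource} table missing columns: {sorted(missing)}")
    return df


def filter_ctd_direct(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows with direct 'marker/mechanism' evidence, order preserved."""
    if "evidence" not in table.columns:
        raise SchemaError("CTD table has no 'evidence' column")
    return table[table["evidence"] == CTD_DIRECT_EVIDENCE].copy()


def filter_gwas_pvalue(table: pd.DataFrame, threshold: float = GWAS_P_THRESHOLD) -> pd.DataFrame:
    """Keep rows with p_value <= threshold (inclusive), order preserved."""
    if "p_value" not in table.columns:
        raise SchemaError("GWAS table has no 'p_value' column")
    p = pd.to_numeric(table["p_value"], errors="coerce")
    bad = table.index[p.isna() & table["p_value"].notna()]
    if len(bad):
        raise SchemaError(
            f"non-numeric p_value in rows {list(bad[:5])}"
            + ("..." if len(bad) > 5 else "")
        )
    return table[p <= threshold].copy()


@dataclass(frozen=True)
class GwasLocus:
    """One reported association: a genomic interval with its primary gene."""

    disease_id: str
    chrom: str
    start: int
    end: int
    reported_gene: str
    p_value: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise SchemaError(
                f"bad locus coordinates [{self.start}, {self.end}) "
                f"for {self.disease_id}/{self.reported_gene}"
            )
        if not (0 < self.p_value <= 1):
            raise SchemaError(f"p_value out of (0, 1]: {self.p_value}")


@dataclass(frozen=True)
class MergedLocus:
    disease_id: str
    chrom: str
    start: int
    end: int
    primary_gene: str
    p_value: float  # minimum over constituents
    n_constituents: int


def loci_from_table(table: pd.DataFrame, one_based: bool = False) -> list[GwasLocus]:
    """Build loci from a GWAS table; 1-based inclusive sources are converted
    to the internal 0-based half-open convention with ``one_based=True``."""
    shift = 1 if one_based else 0
    return [
        GwasLocus(
            disease_id=str(row.disease_id),
            chrom=str(row.chrom),
            start=int(row.start) - shift,
            end=int(row.end),
            reported_gene=str(row.reported_gene),
            p_value=float(row.p_value),
        )
        for row in table.itertuples()
    ]


def merge_loci(loci) -> list[MergedLocus]:
    """Union overlapping loci per (disease, chromosome); one primary gene each.

    Intervals sharing at least one base are merged into maximal intervals
    by a sort-and-sweep; each merged interval's primary gene is the
    reported gene of its lowest-p constituent (ties broken by the
    lexicographically smallest gene symbol). Output is sorted by
    (disease_id, chrom, start).
    """
    groups: dict[tuple[str, str], list[GwasLocus]] = {}
    for loc in loci:
        groups.setdefault((loc.disease_id, loc.chrom), []).append(loc)

    merged: list[MergedLocus] = []
    for (disease_id, chrom), members in sorted(groups.items()):
        members.sort(key=lambda l: (l.start, l.end))
        cluster: list[GwasLocus] = []
        cluster_end = None
        for loc in members + [None]:  # sentinel flushes the final cluster
            if cluster and (loc is None or loc.start >= cluster_end):
                best = min(cluster, key=lambda l: (l.p_value, l.reported_gene))
                merged.append(
                    MergedLocus(
                        disease_id=disease_id,
                        chrom=chrom,
                        start=min(l.start for l in cluster),
                        end=cluster_end,
                        primary_gene=best.reported_gene,
                        p_value=best.p_value,
                        n_constituents=len(cluster),
                    )
                )
                cluster = []
                cluster_end = None
            if loc is not None:
                cluster.append(loc)
                cluster_end = loc.end if cluster_end is None else max(cluster_end, loc.end)
    return merged
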