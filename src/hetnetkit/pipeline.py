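"""End-to-end assembly: YAML config -> filtered, id-mapped ResourceStore.

The config maps resource names to file paths and per-resource dialect
flags (source vocabulary, p-value threshold, evidence string, 1-based
coordinates). ``load_store`` runs the whole preparation chain:

1. parse the three ontologies, rooting the tissue ontology if configured;
2. load the gene alias table and phenotype cross-reference map;
3. register node vocabularies (non-obsolete phenotype/tissue/side-effect
   terms; genes by HGNC integer with current symbols as labels);
4. infer phenotype-tissue and side_effect-tissue edges by propagating the
   manual high-level mappings down each ontology;
5. read each edge table, apply its inclusion filter (CTD direct evidence,
   GWAS significance + locus merging), resolve gene symbols and map
   phenotype ids, and add typed edges to the store.

Gene symbols that fail to resolve uniquely (unknown, or ambiguous alias)
are dropped and counted in the returned context, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ingest
from .construct import ResourceStore
from .idmap import AliasTable, XrefMap
from .ontology import Ontology, parse_obo, propagate_annotations

__all__ = ["PipelineContext", "load_config", "load_store"]


@dataclass
class PipelineContext:
    """Book-keeping from a pipeline run."""

    ontologies: dict[str, Ontology] = field(default_factory=dict)
    alias_table: AliasTable | None = None
    xref_map: XrefMap | None = None
    dropped_genes: dict[str, int] = field(default_factory=dict)  # resource -> rows
    row_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _read_manual_map(path) -> dict[str, set[str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.term_id, set()).add(row.tissue_id)
    return out


def load_store(config_path) -> tuple[ResourceStore, PipelineContext]:
    cfg = load_config(config_path)
    base = Path(config_path).parent

    def p(rel) -> Path:
        return base / rel

    ctx = PipelineContext()
    store = ResourceStore()

    # -- ontologies --------------------------------------------------------
    onts = cfg.get("ontologies", {})
    ont_disease = parse_obo(p(onts["disease"]["path"]))
    tissue_cfg = onts["tissue"]
    ont_tissue = parse_obo(p(tissue_cfg["path"]))
    if tissue_cfg.get("root"):
        ont_tissue = ont_tissue.root_at(tissue_cfg["root"])
    ont_se = parse_obo(p(onts["side_effect"]["path"]))
    ctx.ontologies = {"disease": ont_disease, "tissue": ont_tissue,
                      "side_effect": ont_se}

    # -- mappings ----------------------------------------------------------
    maps = cfg.get("mappings", {})
    alias = AliasTable.from_tsv(p(maps["alias"]))
    xref = XrefMap.from_tsv(p(maps["xref"]))
    ctx.alias_table, ctx.xref_map = alias, xref

    # -- node registries ---------------------------------------------------
    for tid in sorted(ont_disease.non_obsolete_ids()):
        store.register_node("phenotype", tid, ont_disease.terms[tid].name)
    for tid in sorted(ont_tissue.non_obsolete_ids()):
        store.register_node("tissue", tid, ont_tissue.terms[tid].name)
    for tid in sorted(ont_se.non_obsolete_ids()):
        store.register_node("side_effect", tid, ont_se.terms[tid].name)
    for sym, hid in sorted(alias.current_index.items()):
        store.register_node("gene", str(hid), sym)

    # -- ontology-inferred tissue edges ------------------------------------
    registered_tissues = set(ont_tissue.non_obsolete_ids())
    for ont, manual_key, ekind in (
        (ont_disease, "disease_tissue", "phenotype-tissue"),
        (ont_se, "side_effect_tissue", "side_effect-tissue"),
    ):
        manual = _read_manual_map(p(maps[manual_key]))
        inferred = propagate_annotations(ont, manual)
        for term in sorted(inferred):
            for tissue in sorted(inferred[term]):
                if tissue in registered_tissues:
                    store.add_edge(ekind, term, tissue)

    # -- gene / phenotype resolution helpers -------------------------------
    def gene_id(symbol: str) -> str | None:
        res = alias.resolve(symbol)
        return str(res.hgnc_id) if res.found else None

    def pheno_id(vocab: str, source_id: str) -> str:
        return xref.map_phenotype(vocab, source_id)

    resources = cfg.get("resources", {})

    def table(name: str):
        rc = resources.get(name)
        if rc is None:
            return None, {}
        return ingest.read_edge_table(p(rc["path"]), name), rc

    # -- phenotype-gene ----------------------------------------------------
    gwas, rc = table("gwas")
    if gwas is not None:
        kept = ingest.filter_gwas_pvalue(
            gwas, float(rc.get("p_threshold", ingest.GWAS_P_THRESHOLD))
        )
        ctx.row_counts["gwas"] = {"total": len(gwas), "kept": len(kept)}
        loci = ingest.loci_from_table(kept, one_based=bool(rc.get("one_based", False)))
        vocab = rc.get("vocab", "EFO")
        dropped = 0
        for ml in ingest.merge_loci(loci):
            gid = gene_id(ml.primary_gene)
            if gid is None:
                dropped += 1
                continue
            store.add_edge("phenotype-gene", pheno_id(vocab, ml.disease_id), gid,
                           p_value=ml.p_value, resource="gwas")
        ctx.dropped_genes["gwas"] = dropped

    ctd, rc = table("ctd_dg")
    if ctd is not None:
        kept = ingest.filter_ctd_direct(ctd)
        ctx.row_counts["ctd_dg"] = {"total": len(ctd), "kept": len(kept)}
        _add_pairs(store, ctx, "ctd_dg", kept, "phenotype-gene",
                   lambda r: (pheno_id(rc.get("vocab", "MeSH"), r.disease_id),
                              gene_id(r.gene)),
                   resource="ctd")

    omim, rc = table("omim")
    if omim is not None:
        ctx.row_counts["omim"] = {"total": len(omim), "kept": len(omim)}
        _add_pairs(store, ctx, "omim", omim, "phenotype-gene",
                   lambda r: (pheno_id(rc.get("vocab", "OMIM"), r.disease_id),
                              gene_id(r.gene)),
                   resource="omim")

    # -- drug layers -------------------------------------------------------
    dd, rc = table("drug_disease")
    if dd is not None:
        ctx.row_counts["drug_disease"] = {"total": len(dd), "kept": len(dd)}
        _add_pairs(store, ctx, "drug_disease", dd, "drug-phenotype",
                   lambda r: (r.drug_id,
                              pheno_id(rc.get("vocab", "MeSH"), r.disease_id)))

    dg, _ = table("drug_gene")
    if dg is not None:
        ctx.row_counts["drug_gene"] = {"total": len(dg), "kept": len(dg)}
        _add_pairs(store, ctx, "drug_gene", dg, "drug-gene",
                   lambda r: (r.drug_id, gene_id(r.gene)))

    dse, _ = table("drug_side_effect")
    if dse is not None:
        ctx.row_counts["drug_side_effect"] = {"total": len(dse), "kept": len(dse)}
        for row in dse.itertuples():
            store.add_edge("drug-side_effect", row.drug_id, row.se_id,
                           frequency=float(row.frequency))

    # -- gene layers -------------------------------------------------------
    gt, _ = table("gene_tissue")
    if gt is not None:
        ctx.row_counts["gene_tissue"] = {"total": len(gt), "kept": len(gt)}
        dropped = 0
        for row in gt.itertuples():
            gid = gene_id(row.gene)
            if gid is None:
                dropped += 1
                continue
            store.add_edge("gene-tissue", gid, row.tissue_id,
                           expression=float(row.expression))
        ctx.dropped_genes["gene_tissue"] = dropped

    mg, _ = table("mirna_gene")
    if mg is not None:
        ctx.row_counts["mirna_gene"] = {"total": len(mg), "kept": len(mg)}
        _add_pairs(store, ctx, "mirna_gene", mg, "mirna-gene",
                   lambda r: (r.mirna_id, gene_id(r.gene)))

    ppi, _ = table("ppi")
    if ppi is not None:
        ctx.row_counts["ppi"] = {"total": len(ppi), "kept": len(ppi)}
        dropped = 0
        for row in ppi.itertuples():
            ga, gb = gene_id(row.gene_a), gene_id(row.gene_b)
            if ga is None or gb is None:
                dropped += 1
                continue
            store.add_edge("gene-gene", ga, gb)
        ctx.dropped_genes["ppi"] = dropped

    return store, ctx


def _add_pairs(store, ctx, table_name, df, ekind, pair_fn, **attrs) -> None:
    """Add one edge per row; rows whose gene fails to resolve are dropped."""
    dropped = 0
    for row in df.itertuples():
        a, b = pair_fn(row)
        if a is None or b is None:
            dropped += 1
            continue
        store.add_edge(ekind, a, b, **attrs)
    if dropped:
        ctx.dropped_genes[table_name] = ctx.dropped_genes.get(table_name, 0) + dropped
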