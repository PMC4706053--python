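"""Synthetic resource directory generator with brute-force ground truth.

Emits, under one directory, everything the pipeline consumes: three OBO
ontologies (disease, tissue, side effect), manual term→tissue mapping
tables, a gene alias table, a phenotype cross-reference table, the nine
edge tables, and a ready-to-use ``resources.yaml``. A single integer seed
controls all randomness; repeated runs are byte-identical.

Alongside the files, ``generate`` writes ``manifest.json`` carrying ground
truth for every downstream step — filter survivor counts, merged GWAS
associations, the tissue-annotation closure, per-kind node/edge counts of
the full network and projection edge counts at several thresholds — all
computed here by standalone brute-force code (row scans, recursive DFS
closures, per-base interval unions, all-pairs intersections) that never
calls the library modules under test.

The generated data encodes testable structure, not statistical realism:
degree distributions, p-value spectra and ontology shapes are simple
random constructs sized for fast tests, not emulations of real databases.
The disease ontology always embeds connective tissue disease (DOID:65)
mapped to connective tissue (BTO:0000421) with at least two descendant
disease terms, so the canonical propagation example is always exercised.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["FixtureSpec", "generate"]

CTD_DIRECT = "marker/mechanism"
CTD_OTHER_EVIDENCE = ("therapeutic", "inferred")


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the synthetic resource directory. Counts are totals per
    table/ontology; fractions are probabilities in [0, 1]."""

    seed: int = 0
    n_disease_terms: int = 40
    n_obsolete_disease: int = 2
    n_tissue_terms: int = 25          # inside the whole-body subtree
    n_nonanimal_tissue_terms: int = 5  # pruned away by rooting
    n_side_effect_terms: int = 20
    n_genes: int = 120
    n_drugs: int = 30
    n_mirnas: int = 12
    frac_outdated_alias: float = 0.15
    frac_synonym_alias: float = 0.15
    frac_xref: float = 0.5            # disease terms carrying a source-vocab xref
    frac_unmapped_source: float = 0.2  # table rows spelled in a vocab with no DO xref
    gwas_rows: int = 150
    gwas_p_threshold: float = 1e-7
    gwas_log10p_range: tuple[float, float] = (-12.0, -4.0)
    ctd_dg_rows: int = 120
    ctd_direct_frac: float = 0.7
    omim_rows: int = 60
    drug_gene_rows: int = 80
    drug_disease_rows: int = 70
    drug_side_effect_rows: int = 60
    gene_tissue_rows: int = 150
    mirna_gene_rows: int = 50
    ppi_rows: int = 150
    n_manual_disease_tissue: int = 5
    n_manual_se_tissue: int = 4

    def validate(self) -> None:
        for name, val in asdict(self).items():
            if name.startswith(("n_", "gwas_rows")) and isinstance(val, int) and val < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_outdated_alias", "frac_synonym_alias", "frac_xref",
                     "frac_unmapped_source", "ctd_direct_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_disease_terms < 4:
            raise ValueError("need at least 4 disease terms (root, DOID:65, 2 children)")
        if self.n_tissue_terms < 2:
            raise ValueError("need at least 2 whole-body tissue terms")


# ---------------------------------------------------------------------------
# brute-force ground-truth helpers (independent of the library modules)

def _bf_ancestor_closure(parents: dict[str, list[str]], term: str) -> set[str]:
    """All strict ancestors of a term by naive recursive DFS."""
    seen: set[str] = set()

    def walk(t: str) -> None:
        for p in parents.get(t, ()):
            if p not in seen:
                seen.add(p)
                walk(p)

    walk(term)
    return seen


def _bf_propagation(parents: dict[str, list[str]], obsolete: set[str],
                    manual: dict[str, list[str]]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for term in parents:
        if term in obsolete:
            continue
        tissues: set[str] = set()
        for src in {term} | _bf_ancestor_closure(parents, term):
            tissues.update(manual.get(src, ()))
        if tissues:
            out[term] = sorted(tissues)
    return out


def _bf_merge_groups(rows: list[dict]) -> list[tuple[str, str]]:
    """(disease, primary_gene) per merged locus via per-base union clusters."""
    groups: dict[tuple[str, str], list[dict]] = {}
    for r in rows:
        groups.setdefault((r["disease"], r["chrom"]), []).append(r)
    out: list[tuple[str, str]] = []
    for (disease, _chrom), members in sorted(groups.items()):
        covered: set[int] = set()
        for m in members:
            covered.update(range(m["start"], m["end"]))
        # connected runs of covered bases = merged intervals
        runs: list[tuple[int, int]] = []
        for b in sorted(covered):
            if runs and b == runs[-1][1]:
                runs[-1] = (runs[-1][0], b + 1)
            else:
                runs.append((b, b + 1))
        for lo, hi in runs:
            constituents = [m for m in members if m["start"] < hi and m["end"] > lo]
            best = min(constituents, key=lambda m: (m["p"], m["gene"]))
            out.append((disease, best["gene"]))
    return out


def _bf_projection_edge_counts(pairs: set[tuple[str, str]],
                               thresholds: tuple[int, ...]) -> dict[str, int]:
    """All-pairs shared-neighbor counts on a bipartite (left, right) pair set."""
    left = sorted({a for a, _ in pairs})
    nbrs = {a: {b for x, b in pairs if x == a} for a in left}
    counts = dict.fromkeys(thresholds, 0)
    for i, a in enumerate(left):
        for b in left[i + 1:]:
            w = len(nbrs[a] & nbrs[b])
            for t in thresholds:
                if w >= t:
                    counts[t] += 1
    return {str(t): counts[t] for t in thresholds}


# ---------------------------------------------------------------------------
# generation

def _write_obo(path: Path, header_ontology: str, terms: list[dict]) -> None:
    chunks = [f"format-version: 1.2\nontology: {header_ontology}\n"]
    for t in terms:
        lines = [f"[Term]", f"id: {t['id']}", f"name: {t['name']}"]
        for p in t.get("parents", ()):
            lines.append(f"is_a: {p}")
        for x in t.get("xrefs", ()):
            lines.append(f"xref: {x}")
        if t.get("obsolete"):
            lines.append("is_obsolete: true")
        chunks.append("\n".join(lines) + "\n")
    path.write_text("\n".join(chunks))


def _write_tsv(path: Path, columns: list[str], rows: list[tuple]) -> None:
    lines = ["\t".join(columns)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def _random_dag_parents(rng: random.Random, ids: list[str]) -> dict[str, list[str]]:
    """Each term (after the first, the root) points to 1-2 earlier terms."""
    parents: dict[str, list[str]] = {ids[0]: []}
    for i, tid in enumerate(ids[1:], start=1):
        k = 1 if i < 3 or rng.random() < 0.7 else 2
        parents[tid] = sorted(rng.sample(ids[:i], min(k, i)))
    return parents


def generate(spec: FixtureSpec, sink_dir) -> dict:
    """Write the full synthetic resource directory; return the manifest."""
    spec.validate()
    rng = random.Random(spec.seed)
    out = Path(sink_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- disease ontology -------------------------------------------------
    disease_ids = ["DOID:4", "DOID:65", "DOID:650001", "DOID:650002"] + [
        f"DOID:{9000 + i}" for i in range(spec.n_disease_terms - 4)
    ]
    disease_parents = _random_dag_parents(rng, disease_ids)
    # embed the canonical example: DOID:65 under root with two child diseases
    disease_parents["DOID:65"] = ["DOID:4"]
    disease_parents["DOID:650001"] = ["DOID:65"]
    disease_parents["DOID:650002"] = ["DOID:65"]
    obsolete_disease = set(
        rng.sample([d for d in disease_ids if not _is_protected(d)],
                   min(spec.n_obsolete_disease, max(0, len(disease_ids) - 4)))
    )

    # xrefs: some terms get OMIM/MESH/EFO ids; these drive xref.tsv
    xref_rows: list[tuple[str, str, str]] = []   # (vocab, source_id, do_id)
    reverse_xref: dict[str, dict[str, str]] = {"OMIM": {}, "MeSH": {}, "EFO": {}}
    disease_xrefs: dict[str, list[str]] = {d: [] for d in disease_ids}
    counter = 100000
    for d in disease_ids:
        if d in obsolete_disease or d == "DOID:4":
            continue
        if rng.random() < spec.frac_xref:
            for vocab, prefix in (("OMIM", "OMIM"), ("MeSH", "MESH"), ("EFO", "EFO")):
                if rng.random() < 0.6:
                    sid = str(counter)
                    counter += 1
                    xref_rows.append((vocab, sid, d))
                    reverse_xref[vocab][d] = sid
                    disease_xrefs[d].append(f"{prefix}:{sid}")

    disease_terms = [
        {
            "id": d,
            "name": _disease_name(d),
            "parents": disease_parents[d] if d != "DOID:4" else [],
            "xrefs": disease_xrefs[d],
            "obsolete": d in obsolete_disease,
        }
        for d in disease_ids
    ]
    _write_obo(out / "disease.obo", "synthetic-disease-ontology", disease_terms)

    # ---- tissue ontology --------------------------------------------------
    body_ids = ["BTO:0001489", "BTO:0000421"] + [
        f"BTO:{7000 + i:07d}" for i in range(spec.n_tissue_terms - 2)
    ]
    body_parents = _random_dag_parents(rng, body_ids)
    body_parents["BTO:0000421"] = ["BTO:0001489"]
    plant_ids = [f"BTO:{8000 + i:07d}" for i in range(spec.n_nonanimal_tissue_terms)]
    tissue_terms = (
        [{"id": "BTO:0000000", "name": "tissues, cell types and enzyme sources",
          "parents": []}]
        + [{"id": t,
            "name": "whole body" if t == "BTO:0001489"
            else "connective tissue" if t == "BTO:0000421"
            else f"tissue {t[-4:]}",
            "parents": ["BTO:0000000"] if t == "BTO:0001489" else body_parents[t]}
           for t in body_ids]
        + [{"id": t, "name": f"plant tissue {t[-4:]}",
            "parents": [plant_ids[i - 1]] if i else ["BTO:0000000"]}
           for i, t in enumerate(plant_ids)]
    )
    _write_obo(out / "tissue.obo", "synthetic-tissue-ontology", tissue_terms)

    # ---- side-effect ontology --------------------------------------------
    se_ids = [f"SE:{1000 + i}" for i in range(spec.n_side_effect_terms)]
    se_parents = _random_dag_parents(rng, se_ids)
    se_terms = [
        {"id": s, "name": f"side effect {s[3:]}",
         "parents": se_parents[s] if s != se_ids[0] else []}
        for s in se_ids
    ]
    _write_obo(out / "side_effect.obo", "synthetic-side-effect-ontology", se_terms)

    # ---- manual tissue mappings ------------------------------------------
    manual_disease: dict[str, list[str]] = {"DOID:65": ["BTO:0000421"]}
    high_level = [d for d in disease_ids[4:] if d not in obsolete_disease]
    for d in rng.sample(high_level, min(spec.n_manual_disease_tissue - 1, len(high_level))):
        manual_disease.setdefault(d, [])
        tissue = rng.choice(body_ids)
        if tissue not in manual_disease[d]:
            manual_disease[d].append(tissue)
    manual_se: dict[str, list[str]] = {}
    for s in rng.sample(se_ids, min(spec.n_manual_se_tissue, len(se_ids))):
        manual_se[s] = [rng.choice(body_ids)]
    _write_tsv(out / "disease_tissue_manual.tsv", ["term_id", "tissue_id"],
               sorted((d, t) for d, ts in manual_disease.items() for t in ts))
    _write_tsv(out / "side_effect_tissue_manual.tsv", ["term_id", "tissue_id"],
               sorted((s, t) for s, ts in manual_se.items() for t in ts))

    # ---- genes and alias table -------------------------------------------
    symbols = [f"GENE{i + 1}" for i in range(spec.n_genes)]
    hgnc_of = {sym: i + 1 for i, sym in enumerate(symbols)}
    alias_rows: list[tuple[str, int, str]] = [
        (sym, hgnc_of[sym], "current") for sym in symbols
    ]
    unique_alias_of: dict[str, str] = {}  # alias symbol -> current symbol
    for i, sym in enumerate(symbols):
        if rng.random() < spec.frac_outdated_alias:
            alias = f"OLD{i + 1}"
            alias_rows.append((alias, hgnc_of[sym], "outdated"))
            unique_alias_of[alias] = sym
        if rng.random() < spec.frac_synonym_alias:
            alias = f"SYN{i + 1}"
            alias_rows.append((alias, hgnc_of[sym], "synonym"))
            unique_alias_of[alias] = sym
    # one deliberately ambiguous synonym shared by two genes
    ambiguous_alias = None
    if spec.n_genes >= 2:
        ambiguous_alias = "SHAREDSYN"
        alias_rows.append((ambiguous_alias, hgnc_of[symbols[0]], "synonym"))
        alias_rows.append((ambiguous_alias, hgnc_of[symbols[1]], "synonym"))
    _write_tsv(out / "alias.tsv", ["symbol", "hgnc_id", "status"], alias_rows)
    _write_tsv(out / "xref.tsv", ["vocab", "source_id", "do_id"], sorted(xref_rows))

    def spell_gene(sym: str) -> str:
        """Sometimes spell a gene by one of its unique aliases."""
        options = [a for a, s in unique_alias_of.items() if s == sym]
        if options and rng.random() < 0.3:
            return rng.choice(sorted(options))
        return sym

    usable_diseases = sorted(set(disease_ids) - obsolete_disease - {"DOID:4"})

    def spell_disease(vocab: str):
        """(spelled_id, canonical_id): an xref'd DO term spelled in the source
        vocabulary, or an unmapped source id that stays a passthrough node."""
        prefix = {"OMIM": "OMIM", "MeSH": "MESH", "EFO": "EFO"}[vocab]
        mapped = sorted(reverse_xref[vocab].items())
        if mapped and rng.random() >= spec.frac_unmapped_source:
            do_id, sid = rng.choice(mapped)
            return sid, do_id
        sid = str(900000 + rng.randrange(1000))
        return sid, f"{prefix}:{sid}"

    # ---- GWAS table -------------------------------------------------------
    lo, hi = spec.gwas_log10p_range
    gwas_rows: list[tuple] = []
    gwas_truth_rows: list[dict] = []
    n_survivors_gwas = 0
    for _ in range(spec.gwas_rows):
        spelled, canonical = spell_disease("EFO")
        chrom = str(rng.randrange(1, 4))
        start = rng.randrange(0, 5000) * 100
        end = start + rng.randrange(1, 40) * 100
        sym = rng.choice(symbols)
        p_str = f"{10 ** rng.uniform(lo, hi):.6e}"
        p = float(p_str)  # truth must see exactly what the table carries
        gwas_rows.append((spelled, chrom, start, end, spell_gene(sym), p_str))
        if p <= spec.gwas_p_threshold:
            n_survivors_gwas += 1
            gwas_truth_rows.append({"disease": canonical, "chrom": chrom,
                                    "start": start, "end": end,
                                    "gene": sym, "p": p})
    _write_tsv(out / "gwas.tsv",
               ["disease_id", "chrom", "start", "end", "reported_gene", "p_value"],
               gwas_rows)
    merged_assoc = _bf_merge_groups(gwas_truth_rows)
    # merged primary genes are recorded by symbol; canonical gene id is HGNC int
    gwas_pairs = {(d, str(hgnc_of[g])) for d, g in merged_assoc}

    # ---- CTD disease-gene -------------------------------------------------
    ctd_rows: list[tuple] = []
    ctd_pairs: set[tuple[str, str]] = set()
    n_survivors_ctd = 0
    for _ in range(spec.ctd_dg_rows):
        spelled, canonical = spell_disease("MeSH")
        sym = rng.choice(symbols)
        direct = rng.random() < spec.ctd_direct_frac
        evidence = CTD_DIRECT if direct else rng.choice(CTD_OTHER_EVIDENCE)
        ctd_rows.append((spelled, spell_gene(sym), evidence))
        if direct:
            n_survivors_ctd += 1
            ctd_pairs.add((canonical, str(hgnc_of[sym])))
    _write_tsv(out / "ctd_dg.tsv", ["disease_id", "gene", "evidence"], ctd_rows)

    # ---- OMIM disease-gene ------------------------------------------------
    omim_rows: list[tuple] = []
    omim_pairs: set[tuple[str, str]] = set()
    for _ in range(spec.omim_rows):
        spelled, canonical = spell_disease("OMIM")
        sym = rng.choice(symbols)
        omim_rows.append((spelled, spell_gene(sym)))
        omim_pairs.add((canonical, str(hgnc_of[sym])))
    _write_tsv(out / "omim.tsv", ["disease_id", "gene"], omim_rows)

    # ---- drug tables ------------------------------------------------------
    drugs = [f"D{i + 1:04d}" for i in range(spec.n_drugs)]
    drug_gene_rows, drug_gene_pairs = [], set()
    for _ in range(spec.drug_gene_rows):
        drug, sym = rng.choice(drugs), rng.choice(symbols)
        drug_gene_rows.append((drug, spell_gene(sym)))
        drug_gene_pairs.add((drug, str(hgnc_of[sym])))
    _write_tsv(out / "drug_gene.tsv", ["drug_id", "gene"], drug_gene_rows)

    drug_disease_rows, drug_disease_pairs = [], set()
    for _ in range(spec.drug_disease_rows):
        drug = rng.choice(drugs)
        spelled, canonical = spell_disease("MeSH")
        drug_disease_rows.append((drug, spelled))
        drug_disease_pairs.add((drug, canonical))
    _write_tsv(out / "drug_disease.tsv", ["drug_id", "disease_id"], drug_disease_rows)

    drug_se_rows, drug_se_pairs = [], set()
    for _ in range(spec.drug_side_effect_rows):
        drug, se = rng.choice(drugs), rng.choice(se_ids)
        drug_se_rows.append((drug, se, f"{rng.uniform(0.001, 0.6):.4f}"))
        drug_se_pairs.add((drug, se))
    _write_tsv(out / "drug_side_effect.tsv", ["drug_id", "se_id", "frequency"],
               drug_se_rows)

    # ---- gene-tissue, mirna-gene, ppi ------------------------------------
    gene_tissue_rows, gene_tissue_pairs = [], set()
    for _ in range(spec.gene_tissue_rows):
        sym, tissue = rng.choice(symbols), rng.choice(body_ids)
        gene_tissue_rows.append((spell_gene(sym), tissue, f"{rng.uniform(0.1, 900):.2f}"))
        gene_tissue_pairs.add((str(hgnc_of[sym]), tissue))
    _write_tsv(out / "gene_tissue.tsv", ["gene", "tissue_id", "expression"],
               gene_tissue_rows)

    mirnas = [f"hsa-miR-{i + 1}" for i in range(spec.n_mirnas)]
    mirna_rows, mirna_pairs = [], set()
    for _ in range(spec.mirna_gene_rows):
        mir, sym = rng.choice(mirnas), rng.choice(symbols)
        mirna_rows.append((mir, spell_gene(sym)))
        mirna_pairs.add((mir, str(hgnc_of[sym])))
    _write_tsv(out / "mirna_gene.tsv", ["mirna_id", "gene"], mirna_rows)

    ppi_rows, ppi_pairs = [], set()
    for i in range(spec.ppi_rows):
        a = rng.choice(symbols)
        b = a if i == 0 else rng.choice(symbols)  # guarantee one homodimer
        ppi_rows.append((spell_gene(a), spell_gene(b)))
        ia, ib = str(hgnc_of[a]), str(hgnc_of[b])
        ppi_pairs.add((min(ia, ib), max(ia, ib)))
    _write_tsv(out / "ppi.tsv", ["gene_a", "gene_b"], ppi_rows)

    # ---- config -----------------------------------------------------------
    config = f"""ontologies:
  disease:
    path: disease.obo
  tissue:
    path: tissue.obo
    root: BTO:0001489
  side_effect:
    path: side_effect.obo
mappings:
  alias: alias.tsv
  xref: xref.tsv
  disease_tissue: disease_tissue_manual.tsv
  side_effect_tissue: side_effect_tissue_manual.tsv
resources:
  gwas:
    path: gwas.tsv
    vocab: EFO
    p_threshold: {spec.gwas_p_threshold:.1e}
  ctd_dg:
    path: ctd_dg.tsv
    vocab: MeSH
    evidence: marker/mechanism
  omim:
    path: omim.tsv
    vocab: OMIM
  drug_disease:
    path: drug_disease.tsv
    vocab: MeSH
  drug_gene:
    path: drug_gene.tsv
  drug_side_effect:
    path: drug_side_effect.tsv
  gene_tissue:
    path: gene_tissue.tsv
  mirna_gene:
    path: mirna_gene.tsv
  ppi:
    path: ppi.tsv
"""
    (out / "resources.yaml").write_text(config)

    # ---- ground truth -----------------------------------------------------
    disease_parent_map = {d: ([] if d == "DOID:4" else disease_parents[d])
                          for d in disease_ids}
    se_parent_map = {s: (se_parents[s] if s != se_ids[0] else []) for s in se_ids}
    disease_tissue_closure = _bf_propagation(disease_parent_map, obsolete_disease,
                                             manual_disease)
    se_tissue_closure = _bf_propagation(se_parent_map, set(), manual_se)

    phenotype_gene_pairs = gwas_pairs | ctd_pairs | omim_pairs
    pt_edges = sum(len(v) for v in disease_tissue_closure.values())
    st_edges = sum(len(v) for v in se_tissue_closure.values())

    passthrough_phenotypes = {
        d for d, _ in phenotype_gene_pairs if not d.startswith("DOID:")
    } | {c for _, c in drug_disease_pairs if not c.startswith("DOID:")}

    registered_phenotypes = (set(disease_ids) - obsolete_disease) | passthrough_phenotypes
    node_counts = {
        "phenotype": len(registered_phenotypes),
        "gene": spec.n_genes,
        "tissue": len(body_ids),  # whole-body subtree after rooting
        "side_effect": len(se_ids),
        "drug": len({d for d, _ in drug_gene_pairs}
                    | {d for d, _ in drug_disease_pairs}
                    | {d for d, _ in drug_se_pairs}),
        "mirna": len({m for m, _ in mirna_pairs}),
    }
    edge_counts = {
        "phenotype-gene": len(phenotype_gene_pairs),
        "phenotype-tissue": pt_edges,
        "gene-tissue": len(gene_tissue_pairs),
        "drug-phenotype": len(drug_disease_pairs),
        "drug-gene": len(drug_gene_pairs),
        "drug-side_effect": len(drug_se_pairs),
        "side_effect-tissue": st_edges,
        "gene-gene": len(ppi_pairs),
        "mirna-gene": len(mirna_pairs),
    }

    manifest = {
        "seed": spec.seed,
        "spec": {k: v for k, v in asdict(spec).items()},
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "ambiguous_alias": ambiguous_alias,
        "ground_truth": {
            "gwas_rows_total": spec.gwas_rows,
            "gwas_pvalue_survivors": n_survivors_gwas,
            "gwas_merged_associations": len(merged_assoc),
            "gwas_unique_pairs": len(gwas_pairs),
            "ctd_rows_total": spec.ctd_dg_rows,
            "ctd_evidence_survivors": n_survivors_ctd,
            "disease_tissue_closure": {k: disease_tissue_closure[k]
                                       for k in sorted(disease_tissue_closure)},
            "side_effect_tissue_closure": {k: se_tissue_closure[k]
                                           for k in sorted(se_tissue_closure)},
            "node_counts": node_counts,
            "edge_counts": edge_counts,
            "n_nodes_total": sum(node_counts.values()),
            "n_edges_total": sum(edge_counts.values()),
            "projection_phenotype_edges_by_min_shared": _bf_projection_edge_counts(
                phenotype_gene_pairs, (1, 2, 3)
            ),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _is_protected(d: str) -> bool:
    return d in ("DOID:4", "DOID:65", "DOID:650001", "DOID:650002")


def _disease_name(d: str) -> str:
    return {
        "DOID:4": "disease",
        "DOID:65": "connective tissue disease",
        "DOID:650001": "synthetic connective tissue disease A",
        "DOID:650002": "synthetic connective tissue disease B",
    }.get(d, f"synthetic disease {d.split(':')[1]}")
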