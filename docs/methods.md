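# Methods

## The hetnet model

A heterogeneous network (hetnet) is an undirected graph whose nodes and
edges carry semantic types drawn from a metagraph. The default metagraph
registers six node kinds — phenotype, gene, mirna, tissue, drug,
side_effect — and nine edge kinds (see README). The metagraph is cyclic
by construction (disease–gene–drug–disease is a legal triangle of kinds);
no acyclicity is checked or wanted.

Instance networks are backed by a `networkx.MultiGraph` whose edge keys
are edge-kind names: between one node pair there is at most one edge per
kind, and distinct kinds coexist (a drug may be both an indication edge
away and a target edge away from the same neighborhood). The canonical
undirected key is `(min(id), max(id), kind)` by lexicographic id order.
Re-adding an existing edge merges attributes with later-value-wins per
key — deterministic and order-documented. Self-loops (homodimer
protein–protein rows) are accepted and counted once; PPI sources contain
them and nothing in the data model requires excluding them.

Node identity is a namespaced id string. Unification of the same
biological entity across vocabularies is the id-mapping layer's job and
happens *before* insertion; the graph itself never merges nodes.

## Identifier resolution

**Genes.** Nodes are keyed by the integer portion of the HGNC id
(`HGNC:5` → `5`). The alias table holds current symbols plus outdated
symbols and synonyms. Resolution precedence: exact current symbol first,
then a unique alias; an alias pointing at several genes returns an
explicit ambiguous outcome with all candidates. Matching is
case-sensitive (HGNC symbols are case-significant); a case-insensitive
fallback exists behind a flag, default off. Pipeline rows whose gene
cannot be resolved uniquely are dropped and counted, never guessed.

**Phenotypes.** Disease Ontology ids are canonical. OMIM/MeSH/EFO ids
resolve through an explicit cross-reference table; ids without an xref
pass through namespaced (`MESH:D012345`) so unmapped terms stay distinct
nodes rather than silently merging. A source id cross-referenced to
several DO terms raises an ambiguity error listing the candidates —
surfacing, not guessing, is the contract.

## Ontology handling

OBO parsing is delegated to `obonet`; this package's ontology layer adds
the validation the pipeline needs: a dangling `is_a` target is a parse
error naming the offending terms, and an `is_a` cycle is rejected (the
parent relation must be a DAG). Obsolete terms are parsed and flagged but
excluded from node creation and from propagation results — they are
placeholders, not entities.

**Rooting.** `root_at(term)` keeps exactly the term and its descendants,
pruning parent links that point outside. The tissue ontology is rooted at
whole body (BTO:0001489) to discard non-animal branches.

**Tissue-annotation propagation ("ontology inference").** The input is a
small manual map from high-level terms to tissue terms. Every term
receives the union of the manual annotations over itself and all its
`is_a` ancestors; terms with an empty union are absent from the result.
Design choices, made where the procedure was genuinely open:

* Propagation is **downward only** (descendants inherit; an annotated
  term's ancestors receive nothing). Upward propagation is unsupported —
  a disease of a specific tissue says nothing about its siblings'
  tissues.
* Only `is_a` is traversed; `part_of` and other relations are ignored as
  the conservative reading of "more specific terms".
* Multiple annotations on one term are set-unioned, never overwritten.
* Phenotype–tissue and side_effect–tissue edges are produced by the same
  operation applied to their respective ontologies and manual maps.

The operation is idempotent and monotone (a term's result always contains
every annotated ancestor's result); both properties are tested.

## Inclusion filters and locus merging

* CTD disease–gene rows survive only with evidence exactly
  `marker/mechanism` (direct curated evidence, as opposed to therapeutic
  or inferred relationships).
* GWAS rows survive at p ≤ threshold, default 1e-7, **inclusive**:
  genome-wide convention admits boundary hits.
* Coordinates are 0-based half-open internally; 1-based inclusive
  sources convert at read time via a per-resource flag.
* Overlapping loci of one (disease, chromosome) group merge into maximal
  intervals by sort-and-sweep. "Overlapping" is read strictly: intervals
  must share at least one base, so abutting intervals (`[100,200)` and
  `[200,300)`) do not merge. Each merged interval's primary gene is the
  reported gene of its lowest-p constituent; a p tie breaks to the
  lexicographically smallest symbol (determinism over cleverness). This
  is plain interval union — upstream locus-combination methods may differ
  in detail, and the implementation is labeled as the simple union.
* OMIM and CTD rows bypass locus merging; it applies only to the
  SNP→gene conversion of GWAS rows.

Filters are projections: output rows are a subset of input rows and
applying a filter twice equals applying it once (tested on the generated
tables).

## Construction semantics

Building starts from seeds of one kind (phenotype, gene or drug — the
three starting kinds) and expands in two tiers. Within a tier, every
requested edge kind is filtered against the node set **at the start of
that tier** (a phase snapshot), and all additions apply at the phase end;
this makes the result independent of the order in which kinds are listed
and matches a two-phase breadth expansion. After both tiers a closure
pass adds any edge of a requested kind whose endpoints are both already
present (default on, switchable). The closure is what connects tier-2
additions to each other — e.g. protein interactions *among* the
first-degree partners of in-network genes — producing an interconnected
interactome rather than a star. Seeds with no incident edges remain as
isolated nodes: the user asked for them.

`subnetwork_by_min_disease_degree(net, k)` keeps genes linked to ≥ k
distinct phenotypes, the phenotypes they link to, and all edges among
kept nodes (PPIs between kept genes included). With k = 2 this is the
"associated with more than one disease" restriction.

## Projection and topology

Similarity projection connects two nodes of the projected kind iff they
share ≥ `min_shared` neighbors of the via kind, weight = shared count.
The API takes a minimum count, not a strict-greater bound, to avoid
off-by-one ambiguity; "more than 2 shared genes" is `min_shared=3`. The
edge set is monotone non-increasing in the threshold, symmetric, and has
no self-edges (all tested against an all-pairs brute force).

Topology reports count typed hetnet edges (`n_edges`) and separately the
simple-graph edge count (`n_edges_simple`, parallel kinds collapsed,
self-loops dropped). Degree, component, neighborhood-connectivity and
path-length statistics are computed on the simple graph; the degree-sum
identity `Σ d·count(d) = 2·n_edges_simple` is the consistency check. The
N/E ratio is nodes over typed edges, rounded **half-up** to two decimals,
and reported as absent when there are no edges. (Reported figures in the
integration literature are ambiguous about rounding at the second
decimal; half-up is this package's fixed convention.) Because it is not
stated whether published topology panels were computed on full networks
or their largest components, the report exposes both. Largest-component
ties break to the component containing the lexicographically smallest
node id. The all-pairs shortest-path distribution is quadratic in the
largest component; `include_paths=False` skips it for large graphs.

`degree_opacity` scales each node's simple-graph degree by the maximum
within its kind (drug squares shaded by indication sharing); isolated
nodes get 0.0, an all-equal kind gets 1.0 everywhere.

## Synthetic data generator

The generator emulates the *roster* of a public-resource directory — a
disease ontology with cross-references, a rooted tissue ontology with a
non-animal branch to prune, a side-effect hierarchy, an alias table with
outdated/synonym entries and one deliberately shared synonym, and all
nine edge tables spelled in source vocabularies (EFO for GWAS, MeSH for
CTD, OMIM numbers for OMIM) with a configurable unmapped fraction.

Defaults (one choice, fixed): 40 disease terms (2 obsolete), 25
whole-body tissue terms + 5 non-animal, 20 side-effect terms, 120 genes,
30 drugs, 12 miRNAs; 150 GWAS rows with log-uniform p-values over
1e-12..1e-4 so the 1e-7 threshold genuinely bisects them; 120 CTD rows at
70% direct evidence; and 50–150 rows for the remaining tables. These
sizes exercise every code path (filtering, merging, propagation,
passthrough ids, dedup) while keeping the full suite in seconds; they do
not attempt the degree distributions, p-value spectra or ontology shapes
of real databases. Consequently, passing tests demonstrate correctness of
the operations and their composition, not robustness to real-data
pathologies (symbol collisions at scale, deep ontologies, mega-hub
proteins).

Ground truth in `manifest.json` is computed during generation by
standalone brute-force code — per-row scans for filters, recursive DFS
closures for propagation, per-base interval unions for locus merging,
all-pairs set intersections for projection — that never calls the
library modules, so end-to-end equality is a genuine two-route check.
One integer seed controls all randomness; repeated runs are
byte-identical.

## Numerical and degenerate-input conventions

* N/E rounding: decimal half-up at 2 places (`decimal.Decimal`, not
  binary-float `round`).
* Empty networks: zero counts, absent ratio, empty component list;
  `largest_component` of an empty network is the empty network.
* `p_value` must parse as a number in (0, 1]; the error names the rows.
* Interval `start < end` strictly; equal endpoints are a coordinate
  error.
* Node ids may not contain tabs (they would corrupt SIF/TSV exports);
  validated on insert.
* Export ordering is fully sorted, so outputs are diffable and CLI
  results are byte-identical to library calls.

## Known limitations

* No OWL or logical-definition reasoning; OBO tags beyond id/name/is_a/
  xref/is_obsolete are ignored.
* Locus merging is simple interval union; published locus-combination
  procedures may use LD or distance heuristics this package does not.
* Expansion stops at two tiers by design; there is no recursive
  multi-hop traversal or query language.
* No download clients: the package consumes local extracts (or its own
  synthetic directory) only.
* Projection is exact all-pairs set intersection — fine for thousands of
  nodes, not engineered for millions.
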