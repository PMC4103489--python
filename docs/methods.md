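# Methods

## The map-construction procedure

An enrichment map is built in a fixed pipeline:

1. **Parse.** Gene sets (GMT, or embedded in DAVID/BiNGO/GREAT exports),
   enrichment records (GSEA reports, edb directories, generic tables,
   tool dialects), and optional expression (GCT/TXT), ranked lists (RNK)
   and class labels (CLS).
2. **Universe filter.** When expression or ranks are loaded, every gene
   set is intersected with their gene universe; sets emptied by the
   intersection are dropped with a warning. Running this *before* the
   significance filter makes node sizes equal to what the heatmap can
   actually display. (Whether similarity should be computed before or
   after universe filtering is a genuinely open design choice; this
   package declares the order rather than inferring one.)
3. **Significance filter.** A record becomes a node iff
   p ≤ `pvalue_cutoff` and (q absent or q ≤ `qvalue_cutoff`). Records
   without a q-value — the minimal generic format carries only p — are
   filtered on p alone, and the build report says so.
4. **Similarity.** All unordered pairs of node gene sets are scored with
   the configured coefficient; pairs sharing no gene are excluded
   outright. Candidate generation uses an inverted gene→sets index, with
   the contract (enforced by tests) that output is identical to the naive
   all-pairs computation.
5. **Assembly.** Up to two datasets merge on set name; nodes carry
   per-dataset p, q, NES, phenotype and size. Identically named sets with
   different membership take the union for similarity, keep per-dataset
   sizes, and trigger a warning.

All stages are deterministic; nodes and edges are emitted in lexicographic
order so identical inputs serialize byte-identically.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pvalue_cutoff` | 0.05 | max enrichment p for a node (inclusive) |
| `qvalue_cutoff` | 0.1 | max FDR q for a node (inclusive; skipped when q absent) |
| `metric` | OVERLAP | OVERLAP, JACCARD or COMBINED |
| `similarity_cutoff` | 0.5 | min similarity for an edge (inclusive) |
| `combined_k` | 0.5 | overlap weight in the COMBINED blend |
| `strict_similarity` | off | switch the edge boundary from ≥ to > |

All cutoffs are dimensionless fractions in [0, 1]. The COMBINED constant
is set to 0.5 — equal weighting of overlap and Jaccard — as the neutral
choice; it is exposed rather than hard-coded. The boundary convention is
inclusive everywhere (p ≤, q ≤, similarity ≥): one rule for both node and
edge filters keeps the default 0.5 cutoff usable for an exact half-size
overlap. A strict mode is provided for the other convention.

## Conventions and tie-breaks

- **Gene identifiers** are uppercased and stripped before any set
  operation, so GMT, expression and rank files with different casing
  interoperate. Overlap computation must not depend on source casing.
- **Ranked lists** sort descending by score with ties broken by gene id,
  making rank positions (and therefore leading edges) reproducible.
- **Phenotype assignment**: positive direction (NES > 0 or a positive
  generic indicator) maps to phenotype 1, negative to phenotype 2;
  unsigned records report under phenotype 1 with a `neutral` flag that
  exporters translate to a neutral color. For paired GSEA reports the
  file of origin decides direction when NES is absent; when both are
  present and disagree, the NES sign wins with a warning.
- **Leading edge**: for a positively enriched set, members whose 1-based
  rank position is ≤ rank-at-max; for a negatively enriched set, members
  within the last rank-at-max positions of the descending list (negative
  sets accumulate signal from the bottom of the ranking). The enrichment
  score walk itself is not re-derived: rank-at-max is taken from the GSEA
  output, which defines it.
- **Display labels** replace `_`, `%` and `|` in set names with spaces.
  The exact transformation is a declared choice, not a reverse-engineered
  one.
- **Enrichment rows naming no loaded gene set** are warned about and
  dropped — never silently ignored, never given an implicit record. A
  GMT set with no enrichment record is simply not a node.
- **GSEA report columns** are located by case-insensitive,
  punctuation-tolerant header matching, because report versions reorder
  and respell columns; positional parsing is brittle.
- **Tool dialect column maps** (DAVID Term/PValue/Benjamini/Genes; BiNGO
  GO-ID/p-value/corr p-value/last column; GREAT term name with a switch
  between hypergeometric — the default — and binomial statistics) are
  fixed here and covered by fixtures; the tools' documentation names the
  columns but no single canonical export exists.

## Refiltering

`refilter` reproduces interactive cutoff sliders: tightening p, q or the
similarity cutoff on a built network gives exactly the network a rebuild
with those parameters would give, without re-parsing. Loosening is
refused, because filtered records and dropped edges are not retained. The
equivalence is property-tested on a cutoff grid. One caveat: in a
two-dataset map where the same set name has different membership across
datasets, edge scores were computed on the union of member genes, so
refiltering a node down to one dataset keeps the union-based scores; a
rebuild restricted to that dataset could differ. The generators used in
testing share one GMT across datasets, where the two are identical.

## What the synthetic generators emulate

`synth_genesets` plants an exact overlap structure: each cluster's sets
share a common core with disjoint private remainders, so pairwise Jaccard
is a chosen rational *exactly* (shared-gene counting, not sampling) and
similarity expectations in tests are equalities. `synth_enrichments`
plants a significant fraction by drawing p and q inside (outside) the
cutoffs. `synth_expression_bundle` produces two-class expression with
mean shifts for significant-set genes, and a rank file recomputed from
that matrix (standardized mean difference), so expression and ranks are
mutually consistent. `synth_gsea_bundle` writes a well-formed edb
directory whose leading edges are known by construction: planted members
sit inside the leading-edge window, the rest in the middle of the
ranking.

These fixtures exercise the machinery, not the biology: no correlated
pathways, no ontology topology, no realistic p-value distributions.
Passing tests demonstrates that parsing, filtering, similarity, merging,
refiltering and export are correct and deterministic — not that any
particular biological map is recovered from real data.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
similarity-oracle checks use 50 collections of 20–200 sets over a
2,000-gene universe; build/refilter grids use 100-set collections over
6,000 genes; leading-edge checks use 200-gene rankings. These sizes make
every check exact while keeping a full run in the order of seconds.

## Known limitations

- Two datasets at most, by design; the merge keys on set name only.
- The COMBINED blend and the inclusive boundary are declared conventions;
  other implementations of the same idea may choose strict boundaries or
  a different k.
- No network retrieval of gene-set releases; users supply files.
- No layout, clustering or rendering: exports carry style *hints* with
  named colors, and viewers decide the rest.
- The GSEA, DAVID, BiNGO and GREAT statistics themselves are consumed,
  never recomputed.
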