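# enrichmap

Pathway-enrichment results as a similarity network, built headlessly.

A single omics experiment scored against annotation databases routinely
yields hundreds of significantly enriched gene sets, most of them
near-duplicates of each other because pathway databases are highly
redundant. An *enrichment map* tames that list by turning it into a
network: each significantly enriched gene set becomes a node, and two
nodes are connected when they share enough genes, so redundant terms
cluster into themes. This package builds, filters, explores and exports
such maps from the command line or from Python — for computational
biologists who have enrichment results from GSEA, DAVID, BiNGO, GREAT,
g:Profiler-style generic tables or their own tools, and want the network
without a GUI session.

## The model

Nodes are gene sets passing two significance cutoffs (enrichment p-value
and FDR q-value). Edges connect set pairs whose similarity reaches a
cutoff under one of three coefficients on gene membership:

- **Overlap**: |A∩B| / min(|A|, |B|) — 1 when one set contains the other
- **Jaccard**: |A∩B| / |A∪B| — 1 only for identical sets
- **Combined**: k·overlap + (1−k)·Jaccard, a convex blend (default k = 0.5)

Defaults: p ≤ 0.05, q ≤ 0.1, overlap coefficient ≥ 0.5. The p/q cutoffs
control the number of nodes; the similarity cutoff controls the number of
edges. Up to two datasets (e.g. two contrasts) can be merged into one map
with per-dataset statistics side by side. For GSEA inputs, each node's
*leading edge* — the members that contribute most to the enrichment,
bounded by the rank position where the running enrichment score peaks —
can be extracted and highlighted in expression heatmap slices.

## Worked example

```python
from enrichmap import DataSet, build_map, default_parameters, io
from enrichmap.synth import write_micro_files

gmt, enrichments = write_micro_files("demo")
ds = DataSet.from_collections(
    io.read_gmt(gmt), io.read_generic_enrichments(enrichments),
    phenotype1="condition", phenotype2="control",
)
network, report = build_map(ds, default_parameters())
```

This is a 4-set, 6-gene example small enough to verify by hand. It prints
(see `examples/01_build_from_generic.py`):

```
nodes: ['SETA', 'SETB', 'SETC']
edge SETA -- SETB: similarity=0.50 shared=['G3', 'G4']
edge SETA -- SETC: similarity=1.00 shared=['G1', 'G2']
significant: 3 of 4 enrichment records
```

SETD (p = 0.6) fails the p ≤ 0.05 filter, so three nodes remain. SETA and
SETB share 2 of their 4 genes (overlap 0.5, kept at the inclusive default
cutoff); SETC's two genes are both inside SETA (overlap 1.0); SETB and
SETC share nothing. The same map is produced by the command tool:

```sh
enrichmentmap build analysistype=generic gmtFile=demo/micro.gmt \
    enrichmentsDataset1=demo/micro_enrichments.txt --output-dir out
# enrichment map: 3 nodes, 2 edges -> out/map.graphml
```

The CLI mirrors the published command contract (`build` with
`analysistype=GSEA|generic|David|BiNGO|Great`, and `gseabuild` for GSEA
edb directories), accepts the same camelCase `key=value` argument names,
and writes the exported network, a JSON build report and style hints.
Exports: GraphML (lossless round-trip), CX, SIF plus TSV attribute
tables. See `examples/` for similarity metrics, leading-edge extraction,
two-dataset merging with refiltering, and search/heatmap exploration.

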