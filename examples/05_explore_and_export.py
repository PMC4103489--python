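"""Search a built map, slice a heatmap, and export the network.

Search matches every node attribute including member genes, so querying a
gene symbol finds all pathways containing it.  Selecting nodes or edges
yields the corresponding expression rows; the map itself exports to
GraphML/CX/SIF with a JSON style-hint side-car.
"""

import tempfile
from pathlib import Path

from enrichmap import (
    DataSet, build_map, export_network, io, search_nodes, selection_heatmap,
    style_hints,
)
from enrichmap.synth import micro_dataset, synth_expression_bundle

ds = micro_dataset()
# attach a small two-class expression matrix covering the same genes
expr, ranks, classes = synth_expression_bundle(
    seed=5, genesets=list(ds.genesets.values()),
    significant={"SETA", "SETB", "SETC"}, n_samples_per_class=3,
)
ds.expression, ds.ranks, ds.classes = expr, ranks, classes

network, _ = build_map(ds)
print("sets containing G3:", search_nodes(network, "G3"))

edge = network.edges[0]
hm = selection_heatmap(network, [edge], ds)
print(f"heatmap for edge {edge.set_a}--{edge.set_b}: rows={hm.gene_ids}, "
      f"{hm.expression.shape[1]} samples")

with tempfile.TemporaryDirectory() as td:
    files = export_network(network, Path(td) / "map.graphml")
    print("exported:", [Path(f).name for f in files])
hints = style_hints(network)
print("node fill:", hints["node_fill"]["phenotype1"],
      "/", hints["node_fill"]["phenotype2"])
# The style hints document the intended rendering — phenotype1 red,
# phenotype2 blue, node size by gene count, edge width by similarity —
# without tying the export to any particular viewer.
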