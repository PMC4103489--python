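"""Build an enrichment map from a GMT + generic enrichment table.

Uses the bundled 4-set / 6-gene worked example: under the default cutoffs
(p <= 0.05, q <= 0.1, OVERLAP >= 0.5) three sets are significant and two
pairs share enough genes to be connected.
"""

import tempfile
from pathlib import Path

from enrichmap import DataSet, build_map, default_parameters, io
from enrichmap.synth import write_micro_files

with tempfile.TemporaryDirectory() as td:
    gmt, enrichments = write_micro_files(td)
    ds = DataSet.from_collections(
        io.read_gmt(gmt),
        io.read_generic_enrichments(enrichments),
        phenotype1="condition",
        phenotype2="control",
    )
    network, report = build_map(ds, default_parameters())

print(f"nodes: {sorted(network.nodes)}")
for e in network.edges:
    print(f"edge {e.set_a} -- {e.set_b}: similarity={e.similarity:.2f} "
          f"shared={sorted(e.overlap_genes)}")
print(f"significant: {report.enrichments_significant[1]} of "
      f"{report.enrichments_read[1]} enrichment records")
# Each node is a gene set that passed both significance cutoffs; each edge
# connects sets whose overlap coefficient reaches the 0.5 default, with the
# shared genes listed so the "cross-talk" between pathways is explicit.
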