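"""Post-build interrogation of an enrichment map.

Three capabilities mirror how a built map is actually explored:

- :func:`search_nodes` — free-text search over every node attribute,
  including member gene lists, so querying a gene symbol returns every
  set that contains it.
- :func:`selection_heatmap` — the expression sub-matrix for a selection
  of nodes and/or edges (an edge contributes its shared genes), in union
  or intersection mode, with per-gene leading-edge flags.
- :func:`leading_edge_genes` — the members of a GSEA-scored set that
  drive its enrichment, bounded by the rank position where the running
  enrichment score peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import DataSet, EMEdge, EMNetwork, EMNode, EnrichmentResult, RankedList

__all__ = [
    "HeatmapSlice",
    "search_nodes",
    "selection_heatmap",
    "leading_edge_genes",
]


def _node_haystack(node: EMNode, phenotypes) -> list[str]:
    parts = [node.set_name, node.display_label]
    parts.extend(node.genes)
    for i in sorted(node.dataset_membership):
        parts.append(str(node.phenotype.get(i, "")))
        parts.append(str(node.pvalue.get(i, "")))
        q = node.qvalue.get(i)
        if q is not None:
            parts.append(str(q))
        n = node.nes.get(i)
        if n is not None:
            parts.append(str(n))
    return parts


def search_nodes(network: EMNetwork, query: str) -> list[str]:
    """Case-insensitive substring search over all node attributes.

    The haystack for each node includes its name, display label, member
    genes, phenotypes and statistics, so searching a gene symbol (e.g.
    ``TBX20``) returns every gene set containing that gene as well as any
    set whose name mentions it.  Returns sorted node names.
    """
    if not query:
        raise ValueError("search query must be non-empty")
    needle = query.strip().lower()
    hits = []
    for name in network.node_names:
        node = network.nodes[name]
        if any(needle in part.lower() for part in _node_haystack(node, network.phenotypes)):
            hits.append(name)
    return hits


@dataclass
class HeatmapSlice:
    """Expression rows for a selection, with leading-edge annotation."""

    gene_ids: list[str]
    expression: pd.DataFrame  # genes x samples, possibly empty
    leading_edge: dict[str, bool] = field(default_factory=dict)
    mode: str = "union"

    def to_tsv(self, path) -> None:
        """Write the slice as gene, leading-edge flag, sample values."""
        out = self.expression.copy()
        out.insert(0, "leading_edge", [
            "yes" if self.leading_edge.get(g, False) else "no" for g in out.index
        ])
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def _selection_genes(
    selection: Iterable[EMNode | EMEdge | str],
    network: EMNetwork,
) -> list[frozenset[str]]:
    groups = []
    for item in selection:
        if isinstance(item, str):
            item = network.nodes[item]
        if isinstance(item, EMNode):
            groups.append(item.genes)
        elif isinstance(item, EMEdge):
            groups.append(item.overlap_genes)
        else:
            raise TypeError(f"selection items must be nodes or edges, got {item!r}")
    return groups


def selection_heatmap(
    network: EMNetwork,
    selection: Iterable[EMNode | EMEdge | str],
    ds: DataSet,
    mode: str = "union",
    leading_edge: Optional[Iterable[str]] = None,
) -> HeatmapSlice:
    """Expression sub-matrix for selected nodes and edges.

    Union mode shows every gene in any selected element; intersection mode
    only the genes common to all of them (possibly none — an empty slice
    is valid).  An edge contributes its shared genes.  Row order follows
    the dataset's ranked list when present, else expression-file order.
    Node names may be passed in place of node objects.
    """
    if ds.expression is None:
        raise ValueError("no expression matrix loaded for this dataset")
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    groups = _selection_genes(selection, network)
    if not groups:
        raise ValueError("selection is empty")
    if mode == "union":
        genes = frozenset().union(*groups)
    else:
        genes = groups[0]
        for g in groups[1:]:
            genes = genes & g

    available = [g for g in ds.expression.gene_ids if g in genes]
    if ds.ranks is not None:
        pos = {g: i for i, g in enumerate(ds.ranks.gene_ids)}
        available.sort(key=lambda g: (pos.get(g, len(pos)), g))
    le = frozenset(leading_edge or ())
    return HeatmapSlice(
        gene_ids=available,
        expression=ds.expression.values.loc[available],
        leading_edge={g: g in le for g in available},
        mode=mode,
    )


def leading_edge_genes(
    result: EnrichmentResult,
    set_genes: Iterable[str],
    ranks: RankedList,
) -> frozenset[str]:
    """Members of a gene set that contribute most to a GSEA enrichment.

    GSEA's leading edge is bounded by the rank position where the running
    enrichment score peaks (``rank_at_max``).  For a positively enriched
    set these are the members within the first ``rank_at_max`` positions
    of the descending ranked list; for a negatively enriched set, the
    members within the last ``rank_at_max`` positions (negative sets
    accumulate their signal from the bottom of the ranking).  Always a
    subset of the member genes.
    """
    if result.source_dialect != "gsea":
        raise ValueError(
            "leading-edge extraction requires a GSEA result "
            f"(got dialect {result.source_dialect!r})"
        )
    if result.rank_at_max is None:
        raise ValueError(
            f"result {result.set_name!r} has no rank_at_max; the leading edge "
            "is defined by the rank where the enrichment score peaks"
        )
    members = frozenset(set_genes)
    n = len(ranks)
    k = min(result.rank_at_max, n)
    if result.direction == "neg":
        window = ranks.gene_ids[n - k:]
    else:
        window = ranks.gene_ids[:k]
    return members & frozenset(window)
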