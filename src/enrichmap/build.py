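"""The map-construction pipeline.

Stages, in fixed order: parse (done by callers via :mod:`enrichmap.io`),
universe filtering (intersect gene sets with the expression/rank gene
universe), significance filtering (p and q cutoffs select the nodes),
similarity scoring (edges), assembly (merge up to two datasets into one
network).  Running the significance filter after universe filtering keeps
node sizes consistent with what the heatmap can display.

:func:`refilter` reproduces the interactive cutoff-slider semantics:
tightening cutoffs on a built network is equivalent to rebuilding from the
inputs with the new parameters, without re-parsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    BuildParameters,
    DataSet,
    EMEdge,
    EMNetwork,
    EMNode,
    EnrichmentResult,
    GeneSet,
    validate_dataset,
)
from .similarity import pairwise_edges

__all__ = [
    "BuildReport",
    "filter_enrichments",
    "apply_universe_filter",
    "assign_phenotype",
    "build_map",
    "refilter",
    "display_label",
]

log = logging.getLogger(__name__)


@dataclass
class BuildReport:
    """Stage-by-stage counts and warnings from one build."""

    sets_read: dict[int, int] = field(default_factory=dict)
    enrichments_read: dict[int, int] = field(default_factory=dict)
    enrichments_significant: dict[int, int] = field(default_factory=dict)
    unresolved: dict[int, int] = field(default_factory=dict)
    emptied_by_universe: dict[int, int] = field(default_factory=dict)
    nodes_per_dataset: dict[int, int] = field(default_factory=dict)
    nodes_total: int = 0
    candidate_edges: int = 0
    kept_edges: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        log.warning(message)


def filter_enrichments(
    enrichments: Sequence[EnrichmentResult], params: BuildParameters
) -> list[EnrichmentResult]:
    """Select significant records: p <= cutoff and (q absent or q <= cutoff).

    Records without a q-value (the minimal generic format carries only p)
    are filtered on p alone.
    """
    return [
        r
        for r in enrichments
        if r.pvalue <= params.pvalue_cutoff
        and (r.qvalue is None or r.qvalue <= params.qvalue_cutoff)
    ]


def apply_universe_filter(
    genesets: dict[str, GeneSet],
    universe: Optional[frozenset[str]],
    report: Optional[BuildReport] = None,
    dataset_index: int = 1,
) -> dict[str, GeneSet]:
    """Intersect every gene set with the expression/rank gene universe.

    With no universe loaded this is the identity.  Sets that become empty
    are dropped with a warning; they can never be displayed in the
    heatmap, and keeping them would make node sizes inconsistent with it.
    """
    if universe is None:
        return dict(genesets)
    out: dict[str, GeneSet] = {}
    emptied = 0
    for name, gs in genesets.items():
        kept = gs.genes & universe
        if not kept:
            emptied += 1
            if report is not None:
                report.warn(
                    f"dataset {dataset_index}: gene set {name!r} has no genes in "
                    "the expression/rank universe and was dropped"
                )
            continue
        out[name] = GeneSet(name=gs.name, description=gs.description, genes=kept)
    if report is not None:
        report.emptied_by_universe[dataset_index] = emptied
    return out


def assign_phenotype(
    result: EnrichmentResult, ds: DataSet
) -> tuple[str, bool]:
    """Map an enrichment record to a phenotype label.

    Positive direction (NES > 0, or positive generic indicator) means the
    first phenotype, negative the second.  Unsigned records are reported
    under the first phenotype with a neutral flag so exporters can color
    them neutrally.  Returns ``(label, neutral)``.
    """
    if result.direction == "pos":
        return ds.phenotype1, False
    if result.direction == "neg":
        return ds.phenotype2, False
    return ds.phenotype1, True


def display_label(set_name: str) -> str:
    """Human-readable node label: separators become spaces.

    ``APOPTOSIS%REACTOME%R-HSA-109581`` and ``GO_HEART_DEVELOPMENT`` both
    become space-separated words.
    """
    label = set_name
    for sep in ("_", "%", "|"):
        label = label.replace(sep, " ")
    return " ".join(label.split())


def _dataset_nodes(
    ds: DataSet,
    index: int,
    params: BuildParameters,
    report: BuildReport,
) -> tuple[dict[str, GeneSet], dict[str, EnrichmentResult]]:
    """Universe-filter then significance-filter one dataset.

    Returns the filtered gene sets restricted to significant, resolvable
    records, plus the significant record per set name.
    """
    report.sets_read[index] = len(ds.genesets)
    report.enrichments_read[index] = len(ds.enrichments)
    filtered_sets = apply_universe_filter(
        ds.genesets, ds.universe, report, dataset_index=index
    )
    significant = filter_enrichments(ds.enrichments, params)
    report.enrichments_significant[index] = len(significant)

    records: dict[str, EnrichmentResult] = {}
    unresolved = 0
    for r in significant:
        if r.set_name not in filtered_sets:
            unresolved += 1
            why = (
                "not in the GMT"
                if r.set_name not in ds.genesets
                else "emptied by the universe filter"
            )
            report.warn(
                f"dataset {index}: significant set {r.set_name!r} dropped ({why})"
            )
            continue
        if r.set_name in records:
            # two reports for one dataset (e.g. GSEA pos+neg) may both list
            # a set; keep the more significant record
            if r.pvalue < records[r.set_name].pvalue:
                records[r.set_name] = r
            continue
        records[r.set_name] = r
    report.unresolved[index] = unresolved
    node_sets = {name: filtered_sets[name] for name in records}
    report.nodes_per_dataset[index] = len(node_sets)
    return node_sets, records


def build_map(
    datasets: Sequence[DataSet] | DataSet,
    params: Optional[BuildParameters] = None,
    provenance: Optional[dict] = None,
) -> tuple[EMNetwork, BuildReport]:
    """Build an enrichment map from one or two datasets.

    Nodes are the union over datasets of significant, universe-filtered
    gene sets, carrying per-dataset statistics side by side.  Edges come
    from pairwise similarity over the union of node gene sets.  Output is
    deterministic for identical inputs.  Zero nodes after filtering yields
    an empty network with a warning, not an error.
    """
    if isinstance(datasets, DataSet):
        datasets = [datasets]
    if not 1 <= len(datasets) <= 2:
        raise ValueError(
            f"an enrichment map supports 1 or 2 datasets, got {len(datasets)}"
        )
    if params is None:
        params = BuildParameters()
    report = BuildReport()

    for i, ds in enumerate(datasets, start=1):
        errors = [m for sev, m in validate_dataset(ds) if sev == "error"]
        if errors:
            raise ValueError(f"dataset {i} failed validation: {errors[0]}")

    per_ds: dict[int, tuple[dict[str, GeneSet], dict[str, EnrichmentResult]]] = {}
    for i, ds in enumerate(datasets, start=1):
        per_ds[i] = _dataset_nodes(ds, i, params, report)

    # merge node gene sets across datasets; identically named sets with
    # different membership take the union for similarity, with a warning
    merged_genes: dict[str, frozenset[str]] = {}
    for i, (node_sets, _) in per_ds.items():
        for name, gs in node_sets.items():
            if name in merged_genes:
                if merged_genes[name] != gs.genes:
                    report.warn(
                        f"gene set {name!r} differs between datasets; "
                        "using the union for similarity"
                    )
                merged_genes[name] = merged_genes[name] | gs.genes
            else:
                merged_genes[name] = gs.genes

    nodes: dict[str, EMNode] = {}
    for name in sorted(merged_genes):
        membership = frozenset(i for i in per_ds if name in per_ds[i][0])
        pvalue, qvalue, nes, phenotype, neutral, sizes = {}, {}, {}, {}, {}, {}
        for i in sorted(membership):
            record = per_ds[i][1][name]
            pvalue[i] = record.pvalue
            qvalue[i] = record.qvalue
            nes[i] = record.nes
            label, is_neutral = assign_phenotype(record, datasets[i - 1])
            phenotype[i] = label
            neutral[i] = is_neutral
            sizes[i] = per_ds[i][0][name].size
        nodes[name] = EMNode(
            set_name=name,
            display_label=display_label(name),
            dataset_membership=membership,
            pvalue=pvalue,
            qvalue=qvalue,
            nes=nes,
            phenotype=phenotype,
            neutral=neutral,
            genes=merged_genes[name],
            per_dataset_size=sizes,
        )

    report.nodes_total = len(nodes)
    if not nodes:
        report.warn("no gene set passed the significance filters; map is empty")

    scores = pairwise_edges(merged_genes, params) if nodes else []
    edges = [
        EMEdge(
            set_a=s.set_a,
            set_b=s.set_b,
            similarity=s.value,
            overlap_genes=s.overlap,
        )
        for s in scores
    ]
    report.candidate_edges = len(merged_genes) * (len(merged_genes) - 1) // 2
    report.kept_edges = len(edges)

    phenotypes = {
        i: (ds.phenotype1, ds.phenotype2) for i, ds in enumerate(datasets, start=1)
    }
    network = EMNetwork(
        nodes=nodes,
        edges=edges,
        parameters=params,
        provenance=dict(provenance or {}),
        phenotypes=phenotypes,
    )
    log.info(
        "built map: %d nodes, %d edges (metric=%s, cutoff=%g)",
        len(nodes), len(edges), params.metric, params.similarity_cutoff,
    )
    return network, report


def refilter(network: EMNetwork, params: BuildParameters) -> EMNetwork:
    """Re-apply cutoffs to a built network (slider semantics).

    Equivalent to rebuilding with the new parameters, provided every new
    cutoff is at least as strict as the one the network was built with;
    loosening requires data the network no longer holds and is an error.
    The similarity metric cannot change (scores would need recomputing
    from the raw gene sets).
    """
    old = network.parameters
    if params.metric != old.metric or params.combined_k != old.combined_k:
        raise ValueError("refilter cannot change the similarity metric; rebuild")
    if params.pvalue_cutoff > old.pvalue_cutoff:
        raise ValueError(
            f"cannot loosen p cutoff from {old.pvalue_cutoff} to "
            f"{params.pvalue_cutoff}: filtered records are not retained"
        )
    if params.qvalue_cutoff > old.qvalue_cutoff:
        raise ValueError(
            f"cannot loosen q cutoff from {old.qvalue_cutoff} to "
            f"{params.qvalue_cutoff}: filtered records are not retained"
        )
    if params.similarity_cutoff < old.similarity_cutoff:
        raise ValueError(
            f"cannot loosen similarity cutoff from {old.similarity_cutoff} to "
            f"{params.similarity_cutoff}: dropped edges are not retained"
        )

    def node_passes(node: EMNode) -> frozenset[int]:
        kept = []
        for i in node.dataset_membership:
            p = node.pvalue[i]
            q = node.qvalue[i]
            if p <= params.pvalue_cutoff and (q is None or q <= params.qvalue_cutoff):
                kept.append(i)
        return frozenset(kept)

    new_nodes: dict[str, EMNode] = {}
    for name, node in network.nodes.items():
        membership = node_passes(node)
        if not membership:
            continue
        if membership == node.dataset_membership:
            new_nodes[name] = node
        else:
            pick = lambda m: {i: m[i] for i in sorted(membership)}  # noqa: E731
            new_nodes[name] = EMNode(
                set_name=node.set_name,
                display_label=node.display_label,
                dataset_membership=membership,
                pvalue=pick(node.pvalue),
                qvalue=pick(node.qvalue),
                nes=pick(node.nes),
                phenotype=pick(node.phenotype),
                neutral=pick(node.neutral),
                genes=node.genes,
                per_dataset_size=pick(node.per_dataset_size),
            )

    def edge_passes(e: EMEdge) -> bool:
        if e.set_a not in new_nodes or e.set_b not in new_nodes:
            return False
        if params.strict_similarity:
            return e.similarity > params.similarity_cutoff
        return e.similarity >= params.similarity_cutoff

    new_edges = [e for e in network.edges if edge_passes(e)]
    return EMNetwork(
        nodes=new_nodes,
        edges=new_edges,
        parameters=params,
        provenance=dict(network.provenance),
        phenotypes=dict(network.phenotypes),
    )
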