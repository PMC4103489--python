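"""Core domain types for enrichment-map construction.

An enrichment map is a network whose nodes are significantly enriched gene
sets and whose edges encode shared-gene similarity.  The types here are the
in-memory contract shared by the parsers, the similarity engine, the build
pipeline and the exporters.

Gene identifiers are normalized (uppercased, surrounding whitespace
stripped) before any set operation, so inputs with mixed casing
interoperate; see :func:`normalize_gene`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "normalize_gene",
    "GeneSet",
    "EnrichmentResult",
    "ExpressionMatrix",
    "RankedList",
    "ClassAssignment",
    "DataSet",
    "BuildParameters",
    "EMNode",
    "EMEdge",
    "EMNetwork",
    "default_parameters",
    "validate_dataset",
    "Direction",
]

# direction of enrichment relative to the two phenotypes
POS = "pos"
NEG = "neg"
UNSIGNED = "unsigned"
Direction = str

DIALECTS = ("gsea", "generic", "david", "bingo", "great")


def normalize_gene(gene: str) -> str:
    """Canonical form of a gene identifier: stripped and uppercased.

    All set algebra (overlap, Jaccard, universe filtering, heatmap row
    lookup) operates on normalized identifiers so that the same gene
    written as ``tbx20`` in an expression file and ``Tbx20`` in a GMT file
    counts as one gene.
    """
    return gene.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (a pathway or GO term)."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")

    @classmethod
    def from_genes(cls, name: str, description: str, genes: Iterable[str]) -> "GeneSet":
        """Build a set with identifier normalization and deduplication."""
        normalized = frozenset(normalize_gene(g) for g in genes if g.strip())
        return cls(name=name.strip(), description=description, genes=normalized)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-gene-set significance record from one enrichment analysis.

    ``pvalue`` is always present; ``qvalue`` (FDR) may be absent for
    minimal generic inputs.  ``nes`` is GSEA's normalized enrichment
    score whose sign indicates the enriched phenotype.  ``rank_at_max``
    (the rank position where the running enrichment score peaks) is only
    meaningful for GSEA results and bounds the leading edge.
    """

    set_name: str
    description: str = ""
    pvalue: float = 1.0
    qvalue: Optional[float] = None
    nes: Optional[float] = None
    direction: Direction = UNSIGNED
    rank_at_max: Optional[int] = None
    source_dialect: str = "generic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(
                f"p-value for {self.set_name!r} out of [0,1]: {self.pvalue}"
            )
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(
                f"q-value for {self.set_name!r} out of [0,1]: {self.qvalue}"
            )
        if self.direction not in (POS, NEG, UNSIGNED):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.nes is not None:
            expected = POS if self.nes > 0 else NEG if self.nes < 0 else UNSIGNED
            if self.direction != expected:
                raise ValueError(
                    f"direction {self.direction!r} inconsistent with NES={self.nes}"
                )
        if self.rank_at_max is not None:
            if self.source_dialect != "gsea":
                raise ValueError("rank_at_max is only valid for GSEA results")
            if self.rank_at_max < 0:
                raise ValueError("rank_at_max must be non-negative")
        if self.source_dialect not in DIALECTS:
            raise ValueError(f"unknown source dialect {self.source_dialect!r}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-gene descriptions."""

    gene_ids: list[str]
    gene_descriptions: list[str]
    sample_names: list[str]
    values: pd.DataFrame  # index = gene_ids, columns = sample_names

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.gene_descriptions):
            raise ValueError("gene ids and descriptions differ in length")
        if self.values.shape != (len(self.gene_ids), len(self.sample_names)):
            raise ValueError(
                f"expression matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_names)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_ids)


@dataclass
class RankedList:
    """Genes ordered by a signed score, descending; ties break by gene id."""

    gene_ids: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("ranked list genes and scores differ in length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene in ranked list")
        order = sorted(
            range(len(self.gene_ids)),
            key=lambda i: (-self.scores[i], self.gene_ids[i]),
        )
        self.gene_ids = [self.gene_ids[i] for i in order]
        self.scores = [self.scores[i] for i in order]

    def __len__(self) -> int:
        return len(self.gene_ids)

    def position(self, gene: str) -> Optional[int]:
        """1-based rank of a gene, or None if absent."""
        try:
            return self.gene_ids.index(gene) + 1
        except ValueError:
            return None

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_ids)


@dataclass
class ClassAssignment:
    """Two-phenotype sample labelling (CLS semantics)."""

    sample_names: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_names) != len(self.labels):
            raise ValueError("sample names and labels differ in length")
        distinct = sorted(set(self.labels), key=self.labels.index)
        if len(distinct) != 2:
            raise ValueError(
                f"class assignment must have exactly 2 distinct labels, got {distinct}"
            )
        self.class_names = distinct


@dataclass
class DataSet:
    """One analysis unit: gene sets, enrichments and optional omics files.

    ``phenotype1`` / ``phenotype2`` name the two contrasted conditions
    (e.g. heart vs tail); positively enriched sets map to phenotype1.
    """

    genesets: dict[str, GeneSet]
    enrichments: list[EnrichmentResult]
    expression: Optional[ExpressionMatrix] = None
    ranks: Optional[RankedList] = None
    classes: Optional[ClassAssignment] = None
    phenotype1: str = "UP"
    phenotype2: str = "DOWN"
    name: str = "dataset"

    @classmethod
    def from_collections(
        cls,
        genesets: Iterable[GeneSet],
        enrichments: Iterable[EnrichmentResult],
        **kwargs,
    ) -> "DataSet":
        gs = {}
        for s in genesets:
            if s.name in gs:
                raise ValueError(f"duplicate gene set name {s.name!r}")
            gs[s.name] = s
        return cls(genesets=gs, enrichments=list(enrichments), **kwargs)

    @property
    def universe(self) -> Optional[frozenset[str]]:
        """Gene universe from expression or ranks, when either is loaded."""
        if self.expression is not None:
            return self.expression.genes
        if self.ranks is not None:
            return self.ranks.genes
        return None


@dataclass(frozen=True)
class BuildParameters:
    """Cutoffs and similarity configuration for a build.

    Nodes are gene sets passing ``pvalue_cutoff`` and ``qvalue_cutoff``;
    edges are pairs whose similarity under ``metric`` reaches
    ``similarity_cutoff``.  ``combined_k`` weights the overlap term in the
    COMBINED metric.  Boundaries are inclusive (p <= cutoff keeps a node,
    score >= cutoff keeps an edge) unless ``strict_similarity`` is set,
    which switches the edge rule to a strict ``>``.
    """

    pvalue_cutoff: float = 0.05
    qvalue_cutoff: float = 0.1
    metric: str = "OVERLAP"
    similarity_cutoff: float = 0.5
    combined_k: float = 0.5
    strict_similarity: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue_cutoff <= 1.0):
            raise ValueError(f"pvalue_cutoff out of [0,1]: {self.pvalue_cutoff}")
        if not (0.0 <= self.qvalue_cutoff <= 1.0):
            raise ValueError(f"qvalue_cutoff out of [0,1]: {self.qvalue_cutoff}")
        if self.metric not in ("OVERLAP", "JACCARD", "COMBINED"):
            raise ValueError(f"unknown similarity metric {self.metric!r}")
        if not (0.0 <= self.similarity_cutoff <= 1.0):
            raise ValueError(
                f"similarity_cutoff out of [0,1]: {self.similarity_cutoff}"
            )
        if not (0.0 <= self.combined_k <= 1.0):
            raise ValueError(f"combined_k out of [0,1]: {self.combined_k}")

    def with_(self, **changes) -> "BuildParameters":
        return replace(self, **changes)


def default_parameters() -> BuildParameters:
    """The published command-tool defaults.

    p-value cutoff 0.05, q-value cutoff 0.1, OVERLAP metric with
    similarity cutoff 0.5; COMBINED blend constant 0.5 (equal weighting).
    """
    return BuildParameters()


@dataclass(frozen=True)
class EMNode:
    """A node of the map: one significant gene set, possibly in two datasets."""

    set_name: str
    display_label: str
    dataset_membership: frozenset[int]  # subset of {1, 2}
    pvalue: Mapping[int, float]
    qvalue: Mapping[int, Optional[float]]
    nes: Mapping[int, Optional[float]]
    phenotype: Mapping[int, str]
    neutral: Mapping[int, bool]  # True when direction was unsigned
    genes: frozenset[str]  # after universe filtering
    per_dataset_size: Mapping[int, int]

    def __post_init__(self) -> None:
        if not self.dataset_membership:
            raise ValueError(f"node {self.set_name!r} belongs to no dataset")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EMEdge:
    """An undirected similarity edge between two gene-set nodes."""

    set_a: str
    set_b: str
    similarity: float
    overlap_genes: frozenset[str]
    interaction_type: str = "geneset_overlap"

    def __post_init__(self) -> None:
        if self.set_a >= self.set_b:
            raise ValueError("edge endpoints must satisfy set_a < set_b")
        if not self.overlap_genes:
            raise ValueError("edge with empty overlap")
        if not (0.0 <= self.similarity <= 1.0):
            raise ValueError(f"similarity out of [0,1]: {self.similarity}")

    @property
    def overlap_size(self) -> int:
        return len(self.overlap_genes)


@dataclass
class EMNetwork:
    """The built enrichment map: nodes, edges, parameters and provenance."""

    nodes: dict[str, EMNode]
    edges: list[EMEdge]
    parameters: BuildParameters
    provenance: dict = field(default_factory=dict)
    phenotypes: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.set_a not in self.nodes or e.set_b not in self.nodes:
                raise ValueError(
                    f"edge {e.set_a}--{e.set_b} references a missing node"
                )
            key = (e.set_a, e.set_b)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def node_names(self) -> list[str]:
        return sorted(self.nodes)

    def node(self, name: str) -> EMNode:
        return self.nodes[name]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EMNetwork({len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"metric={self.parameters.metric})"
        )


def validate_dataset(ds: DataSet) -> list[tuple[str, str]]:
    """Check a dataset for structural problems before building.

    Returns a list of ``(severity, message)`` pairs where severity is
    ``"warning"`` or ``"error"``.  Enrichment rows whose set name does not
    resolve to a loaded gene set are warnings (they are dropped at build
    time, never silently); gene sets emptied by normalization are errors.
    Validation itself never raises.
    """
    report: list[tuple[str, str]] = []
    for result in ds.enrichments:
        if result.set_name not in ds.genesets:
            report.append(
                (
                    "warning",
                    f"enrichment result {result.set_name!r} does not match any "
                    "loaded gene set and will be dropped",
                )
            )
    for name, gs in ds.genesets.items():
        if not gs.genes:
            report.append(("error", f"gene set {name!r} is empty"))
    if ds.expression is not None and ds.classes is not None:
        if len(ds.classes.sample_names) != len(ds.expression.sample_names):
            report.append(
                (
                    "error",
                    "class file sample count "
                    f"({len(ds.classes.sample_names)}) does not match "
                    f"expression ({len(ds.expression.sample_names)})",
                )
            )
    return report
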