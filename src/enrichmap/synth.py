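"""Seeded synthetic-input generators.

Every file format the readers understand can be generated here with known
ground truth, so the whole pipeline is testable without downloading
anything.  Generators are deterministic functions of their seed
(bit-identical output on re-run) and return the expected results alongside
the data they emit: cluster construction is exact shared-gene counting,
never sampling, so similarity expectations are equalities.

The generators emulate the *structure* of real inputs — gene sets with a
planted overlap pattern, enrichment tables with a planted significant
fraction, two-class expression with mean shifts — not realistic biology
(no correlated pathways, no ontology topology).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    ClassAssignment,
    DataSet,
    EnrichmentResult,
    ExpressionMatrix,
    GeneSet,
    RankedList,
)
from . import io as emio

__all__ = [
    "ClusterSpec",
    "GeneSetTruth",
    "synth_genesets",
    "synth_enrichments",
    "synth_expression_bundle",
    "synth_gsea_bundle",
    "micro_dataset",
    "write_micro_files",
    "make_demo",
]


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


@dataclass(frozen=True)
class ClusterSpec:
    """A group of sets sharing a common core.

    ``jaccard`` is the target pairwise Jaccard coefficient within the
    group; the construction is exact.  With Jaccard a/b in lowest terms,
    each set gets a shared core of ``2a * scale`` genes and a private
    remainder of ``(b - a) * scale`` genes, giving pairwise Jaccard
    ``2a / (2a + 2(b-a)) = a/b`` exactly.  ``scale`` multiplies set size.
    """

    n_sets: int
    jaccard: float
    scale: int = 1

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("cluster needs at least one set")
        if not (0.0 <= self.jaccard <= 1.0):
            raise ValueError(
                f"target overlap fraction must be in [0,1], got {self.jaccard}"
            )
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    @property
    def core_size(self) -> int:
        frac = Fraction(self.jaccard).limit_denominator(10**6)
        return 2 * frac.numerator * self.scale

    @property
    def private_size(self) -> int:
        frac = Fraction(self.jaccard).limit_denominator(10**6)
        private = (frac.denominator - frac.numerator) * self.scale
        if self.core_size + private == 0:
            raise ValueError("cluster sets would be empty; increase scale")
        return private

    @property
    def set_size(self) -> int:
        return self.core_size + self.private_size


@dataclass
class GeneSetTruth:
    """Exact expected pairwise similarity for a generated collection."""

    jaccard: dict[tuple[str, str], float] = field(default_factory=dict)
    overlap: dict[tuple[str, str], float] = field(default_factory=dict)

    def expected(self, a: str, b: str, metric: str, k: float = 0.5) -> float:
        key = (a, b) if a < b else (b, a)
        j = self.jaccard.get(key, 0.0)
        o = self.overlap.get(key, 0.0)
        if metric == "JACCARD":
            return j
        if metric == "OVERLAP":
            return o
        return k * o + (1.0 - k) * j


def synth_genesets(
    seed: int,
    n_sets: int,
    universe_size: int,
    cluster_spec: Sequence[ClusterSpec],
    singleton_size: int = 10,
    path: Optional[str] = None,
) -> tuple[list[GeneSet], GeneSetTruth]:
    """Generate gene sets with an exact planted similarity structure.

    Clusters are mutually disjoint (between-cluster similarity is zero);
    sets beyond the cluster allocation become disjoint singletons of
    ``singleton_size`` genes.  Gene identifiers are drawn from a seeded
    permutation of a universe of ``universe_size`` genes.  When ``path``
    is given the collection is also written as GMT.
    """
    if n_sets < 1 or universe_size < 1:
        raise ValueError("n_sets and universe_size must be positive")
    clustered = sum(c.n_sets for c in cluster_spec)
    if clustered > n_sets:
        raise ValueError(
            f"cluster_spec allocates {clustered} sets but n_sets={n_sets}"
        )
    needed = sum(
        c.core_size + c.n_sets * c.private_size for c in cluster_spec
    ) + (n_sets - clustered) * singleton_size
    if needed > universe_size:
        raise ValueError(
            f"construction needs {needed} genes but universe has {universe_size}"
        )

    rng = np.random.default_rng(seed)
    pool = [_gene_name(i + 1) for i in rng.permutation(universe_size)]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = pool[cursor:cursor + n]
        cursor += n
        return out

    genesets: list[GeneSet] = []
    truth = GeneSetTruth()
    set_idx = 0
    for ci, cluster in enumerate(cluster_spec):
        core = take(cluster.core_size)
        names = []
        for _ in range(cluster.n_sets):
            set_idx += 1
            name = f"SET{set_idx:04d}"
            names.append(name)
            private = take(cluster.private_size)
            genesets.append(
                GeneSet.from_genes(name, f"cluster {ci + 1}", core + private)
            )
        m, s = cluster.core_size, cluster.set_size
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                key = (names[i], names[j])
                # equal sizes: |A∩B| = m, |A∪B| = 2s - m
                truth.jaccard[key] = m / (2 * s - m) if m else 0.0
                truth.overlap[key] = m / s if m else 0.0
    for _ in range(n_sets - clustered):
        set_idx += 1
        genesets.append(
            GeneSet.from_genes(
                f"SET{set_idx:04d}", "singleton", take(singleton_size)
            )
        )

    if path is not None:
        emio.write_gmt(genesets, path)
    return genesets, truth


def synth_enrichments(
    seed: int,
    genesets: Sequence[GeneSet],
    frac_significant: float,
    direction_split: tuple[float, float] = (0.5, 0.5),
    p_cut: float = 0.05,
    q_cut: float = 0.1,
    path: Optional[str] = None,
) -> tuple[list[EnrichmentResult], dict[str, dict]]:
    """Generate a generic enrichment table with planted significance.

    Exactly ``round(frac_significant * n)`` sets receive p ~ U(0, p_cut]
    and q ~ U(0, q_cut] (so they pass the corresponding cutoffs); the
    rest receive p and q strictly above the cutoffs.  ``direction_split``
    gives the (positive, negative) fractions among significant sets; any
    remainder is unsigned.  Returns the records plus a truth table
    ``name -> {significant, direction}``.
    """
    if not (0.0 <= frac_significant <= 1.0):
        raise ValueError(f"frac_significant out of [0,1]: {frac_significant}")
    f_pos, f_neg = direction_split
    if f_pos < 0 or f_neg < 0 or f_pos + f_neg > 1 + 1e-12:
        raise ValueError(f"bad direction_split {direction_split}")

    rng = np.random.default_rng(seed)
    names = [gs.name for gs in genesets]
    n = len(names)
    n_sig = round(frac_significant * n)
    order = rng.permutation(n)
    sig_names = {names[i] for i in order[:n_sig]}

    sig_list = sorted(sig_names)
    n_pos = round(f_pos * len(sig_list))
    n_neg = round(f_neg * len(sig_list))
    n_neg = min(n_neg, len(sig_list) - n_pos)
    directions = {}
    for i, name in enumerate(sig_list):
        directions[name] = "pos" if i < n_pos else "neg" if i < n_pos + n_neg else "unsigned"

    results: list[EnrichmentResult] = []
    truth: dict[str, dict] = {}
    for gs in genesets:
        significant = gs.name in sig_names
        if significant:
            p = float(rng.uniform(0, p_cut))
            q = float(rng.uniform(0, q_cut))
            direction = directions[gs.name]
        else:
            # strictly above both cutoffs so the filter decision is unambiguous
            p = float(p_cut + (1 - p_cut) * max(rng.random(), 1e-9))
            q = float(q_cut + (1 - q_cut) * max(rng.random(), 1e-9))
            direction = "unsigned"
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                description=gs.description,
                pvalue=p,
                qvalue=q,
                direction=direction,
                source_dialect="generic",
            )
        )
        truth[gs.name] = {"significant": significant, "direction": direction}

    if path is not None:
        with open(path, "w") as fh:
            for r in results:
                sign = {"pos": "1", "neg": "-1", "unsigned": "0"}[r.direction]
                fh.write(
                    f"{r.set_name}\t{r.description}\t{r.pvalue:.6g}\t"
                    f"{r.qvalue:.6g}\t{sign}\n"
                )
    return results, truth


def synth_expression_bundle(
    seed: int,
    genesets: Sequence[GeneSet],
    significant: set[str],
    n_samples_per_class: int = 3,
    shift: float = 2.0,
    phenotypes: tuple[str, str] = ("classA", "classB"),
    outdir: Optional[str] = None,
) -> tuple[ExpressionMatrix, RankedList, ClassAssignment]:
    """Two-class expression with mean shifts for genes in significant sets.

    Genes belonging to any significant set get their class-1 mean raised
    by ``shift`` standard units.  The ranked list is the standardized mean
    difference (class1 − class2, pooled SD) recomputed from the emitted
    matrix, so ranks and expression are consistent by construction.  With
    ``outdir`` set, writes ``expression.txt``, ``ranks.rnk`` and
    ``classes.cls``.
    """
    if n_samples_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(seed)
    genes = sorted(set().union(*(gs.genes for gs in genesets)))
    shifted = set().union(
        *(gs.genes for gs in genesets if gs.name in significant)
    ) if significant else set()
    n1 = n2 = n_samples_per_class
    values = rng.normal(0.0, 1.0, size=(len(genes), n1 + n2))
    for i, g in enumerate(genes):
        if g in shifted:
            values[i, :n1] += shift
    samples = [f"{phenotypes[0]}_{i+1}" for i in range(n1)] + [
        f"{phenotypes[1]}_{i+1}" for i in range(n2)
    ]

    import pandas as pd

    frame = pd.DataFrame(values, index=genes, columns=samples)
    expr = ExpressionMatrix(
        gene_ids=list(genes),
        gene_descriptions=["" for _ in genes],
        sample_names=samples,
        values=frame,
    )

    m1 = values[:, :n1].mean(axis=1)
    m2 = values[:, n1:].mean(axis=1)
    v1 = values[:, :n1].var(axis=1, ddof=1)
    v2 = values[:, n1:].var(axis=1, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    smd = (m1 - m2) / np.where(pooled > 0, pooled, 1.0)
    ranks = RankedList(gene_ids=list(genes), scores=[float(s) for s in smd])

    classes = ClassAssignment(
        sample_names=samples,
        labels=[phenotypes[0]] * n1 + [phenotypes[1]] * n2,
    )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "expression.txt", "w") as fh:
            fh.write("NAME\tDESCRIPTION\t" + "\t".join(samples) + "\n")
            for i, g in enumerate(genes):
                row = "\t".join(f"{v:.6f}" for v in values[i])
                fh.write(f"{g}\tna\t{row}\n")
        with open(out / "ranks.rnk", "w") as fh:
            for g, s in zip(ranks.gene_ids, ranks.scores):
                fh.write(f"{g}\t{s:.6f}\n")
        with open(out / "classes.cls", "w") as fh:
            fh.write(f"{n1 + n2} 2 1\n# {phenotypes[0]} {phenotypes[1]}\n")
            fh.write(" ".join(classes.labels) + "\n")
    return expr, ranks, classes


def synth_gsea_bundle(
    seed: int,
    outdir: str,
    n_sets: int = 4,
    members_leading: int = 3,
    members_rest: int = 3,
    universe_size: int = 100,
    rank_at_max: int = 20,
    frac_negative: float = 0.5,
    omit_gmt: bool = False,
) -> dict:
    """Materialize a GSEA-style edb results directory with known truth.

    The ranked list is a seeded permutation of the universe with strictly
    decreasing scores.  Each set plants ``members_leading`` genes inside
    its leading-edge window — the first ``rank_at_max`` positions for
    positive sets, the last ``rank_at_max`` for negative — and
    ``members_rest`` genes in the middle of the ranking, so the exact
    expected leading edge is known by construction.  The results XML
    carries ES/NES, p, FDR and rank-at-max per set.

    Returns a truth dict with the bundle path, per-set expected leading
    edges, directions and the planted statistics.  ``omit_gmt`` leaves the
    GMT out to exercise the reader's error path.
    """
    if rank_at_max * 2 >= universe_size:
        raise ValueError("rank_at_max windows must not cover the whole ranking")
    if members_leading > rank_at_max:
        raise ValueError("cannot plant more leading genes than the window holds")
    rng = np.random.default_rng(seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    order = [_gene_name(i + 1) for i in rng.permutation(universe_size)]
    scores = np.linspace(3.0, -3.0, universe_size)
    with open(out / "ranked_list.rnk", "w") as fh:
        for g, s in zip(order, scores):
            fh.write(f"{g}\t{s:.6f}\n")

    top = order[:rank_at_max]
    bottom = order[-rank_at_max:]
    middle = order[rank_at_max:-rank_at_max]

    n_neg = round(frac_negative * n_sets)
    truth_sets: dict[str, dict] = {}
    genesets: list[GeneSet] = []
    records = []
    for i in range(n_sets):
        name = f"PATHWAY_{i + 1:02d}"
        negative = i < n_neg
        window = bottom if negative else top
        lead = sorted(rng.choice(len(window), size=members_leading, replace=False))
        lead_genes = [window[j] for j in lead]
        rest = sorted(rng.choice(len(middle), size=members_rest, replace=False))
        rest_genes = [middle[j] for j in rest]
        members = lead_genes + rest_genes
        genesets.append(GeneSet.from_genes(name, "planted", members))
        nes = float(-(1.5 + i * 0.1)) if negative else float(1.5 + i * 0.1)
        p = float(rng.uniform(0, 0.01))
        q = float(rng.uniform(0, 0.05))
        records.append((name, nes, p, q, rank_at_max))
        truth_sets[name] = {
            "members": sorted(members),
            "leading_edge": sorted(lead_genes),
            "direction": "neg" if negative else "pos",
            "nes": nes,
            "pvalue": p,
            "qvalue": q,
            "rank_at_max": rank_at_max,
        }

    if not omit_gmt:
        emio.write_gmt(genesets, out / "gene_sets.gmt")

    dtgs = []
    for name, nes, p, q, ram in records:
        es = nes / 2.0
        dtgs.append(
            f'  <DTG RANKED_LIST="ranked_list.rnk" TEMPLATE="phen" '
            f'GENESET="gene_sets.gmt#{name}" ES="{es:.4f}" NES="{nes:.4f}" '
            f'NP="{p:.6f}" FDR="{q:.6f}" FWER="1.0" RANK_AT_ES="{ram}"/>'
        )
    (out / "results.edb").write_text(
        '<?xml version="1.0" encoding="UTF-8"?>\n<EDB>\n'
        + "\n".join(dtgs)
        + "\n</EDB>\n"
    )
    return {"path": str(out), "sets": truth_sets, "n_sets": n_sets}


# ---------------------------------------------------------------------------
# hand-enumerated worked example

_MICRO_SETS = [
    ("SETA", "micro", ["G1", "G2", "G3", "G4"]),
    ("SETB", "micro", ["G3", "G4", "G5", "G6"]),
    ("SETC", "micro", ["G1", "G2"]),
    ("SETD", "micro", ["G5", "G6"]),
]
# SETD is planted non-significant; under the default cutoffs the map has
# nodes {SETA, SETB, SETC} and, with OVERLAP >= 0.5, the edges
# SETA--SETB (overlap {G3,G4}: 2/4 = 0.5) and SETA--SETC ({G1,G2}: 2/2 = 1)
_MICRO_ENRICHMENTS = [
    ("SETA", "micro", 0.01, 0.01, 1),
    ("SETB", "micro", 0.02, 0.02, 1),
    ("SETC", "micro", 0.03, 0.03, -1),
    ("SETD", "micro", 0.60, 0.70, 0),
]


def micro_dataset() -> DataSet:
    """The 4-set / 6-gene worked example as an in-memory dataset."""
    genesets = [GeneSet.from_genes(n, d, g) for n, d, g in _MICRO_SETS]
    enrichments = [
        EnrichmentResult(
            set_name=n,
            description=d,
            pvalue=p,
            qvalue=q,
            direction="pos" if s > 0 else "neg" if s < 0 else "unsigned",
            source_dialect="generic",
        )
        for n, d, p, q, s in _MICRO_ENRICHMENTS
    ]
    return DataSet.from_collections(
        genesets, enrichments, phenotype1="condition", phenotype2="control"
    )


def write_micro_files(outdir) -> tuple[str, str]:
    """Write the worked example as a GMT + generic enrichment table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gmt = out / "micro.gmt"
    enr = out / "micro_enrichments.txt"
    with open(gmt, "w") as fh:
        for n, d, genes in _MICRO_SETS:
            fh.write("\t".join([n, d, *genes]) + "\n")
    with open(enr, "w") as fh:
        for n, d, p, q, s in _MICRO_ENRICHMENTS:
            fh.write(f"{n}\t{d}\t{p}\t{q}\t{s}\n")
    return str(gmt), str(enr)


def make_demo(seed: int, outdir) -> dict:
    """Materialize a complete demo input directory (every format).

    Writes a clustered GMT, a generic enrichment table, an expression
    bundle (TXT/RNK/CLS) and a GSEA edb directory, and returns the truth
    dictionaries of each generator.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genesets, sim_truth = synth_genesets(
        seed,
        n_sets=12,
        universe_size=600,
        cluster_spec=[
            ClusterSpec(n_sets=4, jaccard=0.5, scale=4),
            ClusterSpec(n_sets=4, jaccard=0.25, scale=3),
        ],
        singleton_size=12,
        path=out / "genesets.gmt",
    )
    results, enr_truth = synth_enrichments(
        seed + 1,
        genesets,
        frac_significant=0.5,
        direction_split=(0.5, 0.5),
        path=out / "enrichments.txt",
    )
    significant = {n for n, t in enr_truth.items() if t["significant"]}
    synth_expression_bundle(
        seed + 2, genesets, significant, outdir=out / "expression"
    )
    gsea_truth = synth_gsea_bundle(seed + 3, out / "edb")
    return {
        "dir": str(out),
        "similarity": sim_truth,
        "enrichments": enr_truth,
        "gsea": gsea_truth,
    }
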