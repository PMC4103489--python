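"""Gene-set similarity coefficients and all-pairs edge candidates.

Three coefficients connect gene sets by shared membership:

- overlap:  |A∩B| / min(|A|, |B|)   (1 when one set contains the other)
- Jaccard:  |A∩B| / |A∪B|           (1 only for identical sets)
- combined: k·overlap + (1−k)·Jaccard, a convex blend with constant k

Since overlap >= Jaccard for any pair, the combined score always lies
between them.  Candidate generation uses an inverted gene -> sets index so
disjoint pairs are never scored; the output is contractually identical to
the naive all-pairs computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .model import BuildParameters, GeneSet

__all__ = ["SimilarityScore", "jaccard", "overlap", "combined", "pairwise_edges"]


@dataclass(frozen=True)
class SimilarityScore:
    """A scored unordered pair of gene sets (set_a < set_b)."""

    set_a: str
    set_b: str
    value: float
    overlap: frozenset[str]


def _check_nonempty(a, b) -> None:
    if not a or not b:
        raise ValueError("similarity coefficients require non-empty gene sets")


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard coefficient |A∩B| / |A∪B|."""
    a, b = set(a), set(b)
    _check_nonempty(a, b)
    return len(a & b) / len(a | b)


def overlap(a: Iterable[str], b: Iterable[str]) -> float:
    """Overlap (Szymkiewicz–Simpson) coefficient |A∩B| / min(|A|, |B|)."""
    a, b = set(a), set(b)
    _check_nonempty(a, b)
    return len(a & b) / min(len(a), len(b))


def combined(a: Iterable[str], b: Iterable[str], k: float = 0.5) -> float:
    """Convex blend k·overlap + (1−k)·Jaccard with k in [0, 1]."""
    if not (0.0 <= k <= 1.0):
        raise ValueError(f"combined constant k must be in [0,1], got {k}")
    a, b = set(a), set(b)
    _check_nonempty(a, b)
    inter = len(a & b)
    return k * (inter / min(len(a), len(b))) + (1.0 - k) * (inter / len(a | b))


def _score(a: frozenset, b: frozenset, params: BuildParameters) -> float:
    inter = len(a & b)
    if params.metric == "OVERLAP":
        return inter / min(len(a), len(b))
    if params.metric == "JACCARD":
        return inter / len(a | b)
    k = params.combined_k
    return k * (inter / min(len(a), len(b))) + (1.0 - k) * (inter / len(a | b))


def _passes(value: float, params: BuildParameters) -> bool:
    if params.strict_similarity:
        return value > params.similarity_cutoff
    return value >= params.similarity_cutoff


def pairwise_edges(
    genesets: Mapping[str, frozenset[str]] | Iterable[GeneSet],
    params: BuildParameters,
) -> list[SimilarityScore]:
    """Score all unordered gene-set pairs and keep those passing the cutoff.

    Pairs with an empty intersection are excluded outright (their score is
    zero under every metric).  An edge is kept when its score reaches the
    similarity cutoff; the boundary is inclusive (>=) by default and strict
    (>) when ``params.strict_similarity`` is set.  Output order is
    deterministic: lexicographic by (set_a, set_b).

    Accepts either a mapping name -> gene frozenset or an iterable of
    :class:`GeneSet`.
    """
    if not isinstance(genesets, Mapping):
        genesets = {gs.name: gs.genes for gs in genesets}
    sets = {name: frozenset(genes) for name, genes in genesets.items()}
    for name, genes in sets.items():
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")

    # inverted index: only pairs sharing at least one gene are candidates
    by_gene: dict[str, list[str]] = {}
    for name in sorted(sets):
        for g in sets[name]:
            by_gene.setdefault(g, []).append(name)
    candidates: set[tuple[str, str]] = set()
    for members in by_gene.values():
        candidates.update(combinations(members, 2))  # members already sorted

    edges: list[SimilarityScore] = []
    for a, b in sorted(candidates):
        value = _score(sets[a], sets[b], params)
        if _passes(value, params):
            edges.append(
                SimilarityScore(
                    set_a=a, set_b=b, value=value, overlap=sets[a] & sets[b]
                )
            )
    return edges
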