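"""File-format readers and writers.

Every input format named by the command tool lives here: GMT gene-set
files, RNK ranked lists, CLS class files, GCT/TXT expression matrices,
GSEA enrichment reports, the GSEA results ``edb`` directory, the minimal
"generic" enrichment table, and the DAVID / BiNGO / GREAT export dialects.

All readers accept a filesystem path, tolerate CRLF line endings and
trailing whitespace, and raise :class:`ParseError` (with file and line
context) or :class:`UnsupportedFileError` rather than crashing on
malformed input.  Record counts are logged at INFO level.
"""

from __future__ import annotations

import logging
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    ClassAssignment,
    EnrichmentResult,
    ExpressionMatrix,
    GeneSet,
    RankedList,
    normalize_gene,
)

__all__ = [
    "ParseError",
    "UnsupportedFileError",
    "EdbBundle",
    "read_gmt",
    "write_gmt",
    "read_generic_enrichments",
    "read_gsea_report",
    "read_edb_directory",
    "read_rank_file",
    "read_class_file",
    "read_expression_matrix",
    "read_tool_enrichments",
]

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed record, reported with file and line context."""

    def __init__(self, path, lineno: Optional[int], message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{self.path}" + (f":{lineno}" if lineno is not None else "")
        super().__init__(f"{where}: {message}")


class UnsupportedFileError(ValueError):
    """The file is structurally not in the expected format/dialect."""


def _lines(path) -> list[str]:
    text = Path(path).read_text()
    # normalize line endings; drop a trailing empty line from final newline
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    return lines


def _float(value: str, path, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {what}: {value!r}") from None


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: per line, name TAB description TAB gene1 TAB gene2...

    Gene identifiers are normalized and deduplicated; blank lines are
    skipped.  Duplicate set names and lines with fewer than three fields
    are parse errors.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise ParseError(
                path, lineno, f"GMT line has {len(fields)} fields, expected >= 3"
            )
        name, description, genes = fields[0], fields[1], fields[2:]
        if name in seen:
            raise ParseError(path, lineno, f"duplicate gene set name {name!r}")
        seen.add(name)
        sets.append(GeneSet.from_genes(name, description, genes))
    log.info("read %d gene sets from %s", len(sets), path)
    return sets


def write_gmt(genesets: Iterable[GeneSet], path) -> None:
    """Write gene sets as GMT; genes are emitted in sorted order."""
    with open(path, "w") as fh:
        for gs in genesets:
            fields = [gs.name, gs.description, *sorted(gs.genes)]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Generic enrichment table

def read_generic_enrichments(path) -> list[EnrichmentResult]:
    """Read the minimal generic enrichment format.

    Tab-separated columns: name, description, p-value, then optionally
    FDR q-value and a signed phenotype indicator (column 5: positive
    numbers mean phenotype1, negative phenotype2).  Lines starting with
    ``#`` are comments.
    """
    results: list[EnrichmentResult] = []
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise ParseError(
                path, lineno, f"generic line has {len(fields)} fields, expected >= 3"
            )
        name, description = fields[0], fields[1]
        pvalue = _float(fields[2], path, lineno, "p-value")
        qvalue = None
        if len(fields) >= 4 and fields[3] != "":
            qvalue = _float(fields[3], path, lineno, "q-value")
        direction = "unsigned"
        if len(fields) >= 5 and fields[4] != "":
            sign = _float(fields[4], path, lineno, "phenotype indicator")
            direction = "pos" if sign > 0 else "neg" if sign < 0 else "unsigned"
        results.append(
            EnrichmentResult(
                set_name=name,
                description=description,
                pvalue=pvalue,
                qvalue=qvalue,
                direction=direction,
                source_dialect="generic",
            )
        )
    log.info("read %d generic enrichment results from %s", len(results), path)
    return results


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# GSEA report

# header-name matching is case-insensitive and punctuation-tolerant because
# GSEA versions vary header spelling ("NOM p-val", "NOM.p.val", ...)
def _canon_header(h: str) -> str:
    return re.sub(r"[^a-z0-9]", "", h.lower())


_GSEA_COLUMNS = {
    "name": ("name",),
    "es": ("es",),
    "nes": ("nes",),
    "pvalue": ("nompval", "nompvalue", "pvalue", "pval"),
    "qvalue": ("fdrqval", "fdrqvalue", "qvalue", "qval"),
    "rank_at_max": ("rankatmax", "rankates"),
}


def read_gsea_report(path) -> list[EnrichmentResult]:
    """Read a GSEA enrichment report (xls-named TSV with a header row).

    Columns are located by header name, not position: NAME, ES, NES,
    nominal p-value, FDR q-value and rank-at-max.  Blank numeric cells
    become absent values.  A report missing NAME or the p column is
    rejected as unsupported.
    """
    lines = _lines(path)
    if not lines:
        raise UnsupportedFileError(f"{path}: empty GSEA report")
    header = [_canon_header(h) for h in lines[0].split("\t")]
    col: dict[str, int] = {}
    for key, aliases in _GSEA_COLUMNS.items():
        for i, h in enumerate(header):
            if h in aliases:
                col[key] = i
                break
    if "name" not in col or "pvalue" not in col:
        raise UnsupportedFileError(
            f"{path}: not a GSEA report (missing NAME or nominal p-value header)"
        )

    def cell(fields: Sequence[str], key: str) -> Optional[str]:
        i = col.get(key)
        if i is None or i >= len(fields):
            return None
        v = fields[i].strip()
        return v or None

    results: list[EnrichmentResult] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        name = cell(fields, "name")
        if name is None:
            raise ParseError(path, lineno, "missing NAME value")
        p_raw = cell(fields, "pvalue")
        pvalue = _float(p_raw, path, lineno, "p-value") if p_raw is not None else 1.0
        q_raw = cell(fields, "qvalue")
        qvalue = _float(q_raw, path, lineno, "q-value") if q_raw is not None else None
        nes_raw = cell(fields, "nes")
        nes = _float(nes_raw, path, lineno, "NES") if nes_raw is not None else None
        if nes is not None and math.isnan(nes):
            nes = None
        ram_raw = cell(fields, "rank_at_max")
        rank_at_max = (
            int(_float(ram_raw, path, lineno, "rank at max"))
            if ram_raw is not None
            else None
        )
        direction = "unsigned"
        if nes is not None:
            direction = "pos" if nes > 0 else "neg" if nes < 0 else "unsigned"
        results.append(
            EnrichmentResult(
                set_name=name,
                description=name,
                pvalue=pvalue,
                qvalue=qvalue,
                nes=nes,
                direction=direction,
                rank_at_max=rank_at_max,
                source_dialect="gsea",
            )
        )
    log.info("read %d GSEA report rows from %s", len(results), path)
    return results


# ---------------------------------------------------------------------------
# GSEA edb directory

@dataclass
class EdbBundle:
    """The three components of a GSEA results ``edb`` directory.

    GSEA writes its full results as a directory holding a GMT of the gene
    sets analyzed, the ranked list used, and a ``results.edb`` XML whose
    per-set records carry ES/NES, p, FDR and the rank at which the running
    enrichment score peaks.
    """

    directory: str
    gene_sets: list[GeneSet]
    ranks: RankedList
    results: list[EnrichmentResult]


def read_edb_directory(path) -> EdbBundle:
    """Assemble an :class:`EdbBundle` from a GSEA edb directory."""
    d = Path(path)
    if not d.is_dir():
        raise UnsupportedFileError(f"{d}: not a directory")
    xmls = sorted(d.glob("*.edb"))
    gmts = sorted(d.glob("*.gmt"))
    rnks = sorted(p for p in d.iterdir() if p.suffix.lower() in (".rnk", ".rank"))
    if not xmls:
        raise UnsupportedFileError(f"{d}: no .edb results XML found")
    if not gmts:
        raise UnsupportedFileError(f"{d}: no .gmt gene set file found")
    if not rnks:
        raise UnsupportedFileError(f"{d}: no rank (.rnk) file found")
    gene_sets = read_gmt(gmts[0])
    ranks = read_rank_file(rnks[0])
    results = _read_edb_xml(xmls[0])
    log.info(
        "edb bundle %s: %d sets, %d ranked genes, %d results",
        d, len(gene_sets), len(ranks), len(results),
    )
    return EdbBundle(
        directory=str(d), gene_sets=gene_sets, ranks=ranks, results=results
    )


def _read_edb_xml(path) -> list[EnrichmentResult]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ParseError(path, None, f"invalid XML: {exc}") from None
    results: list[EnrichmentResult] = []
    for dtg in tree.getroot().iter("DTG"):
        geneset = dtg.get("GENESET", "")
        # GENESET is "gene_sets.gmt#SET_NAME"
        name = geneset.split("#", 1)[1] if "#" in geneset else geneset
        if not name:
            raise ParseError(path, None, "DTG record without GENESET attribute")
        nes = _attr_float(dtg, "NES")
        pvalue = _attr_float(dtg, "NP")
        qvalue = _attr_float(dtg, "FDR")
        ram = _attr_float(dtg, "RANK_AT_ES")
        direction = "unsigned"
        if nes is not None:
            direction = "pos" if nes > 0 else "neg" if nes < 0 else "unsigned"
        results.append(
            EnrichmentResult(
                set_name=name,
                description=name,
                pvalue=pvalue if pvalue is not None else 1.0,
                qvalue=qvalue,
                nes=nes,
                direction=direction,
                rank_at_max=int(ram) if ram is not None else None,
                source_dialect="gsea",
            )
        )
    return results


def _attr_float(elem, attr: str) -> Optional[float]:
    v = elem.get(attr)
    if v is None or v.strip() == "":
        return None
    return float(v)


# ---------------------------------------------------------------------------
# RNK

def read_rank_file(path) -> RankedList:
    """Read a two-column RNK file (gene, score).

    An optional header is detected by a non-numeric second field on the
    first line.  Output order is descending by score with ties broken by
    gene id; duplicate genes are an error.
    """
    gene_ids: list[str] = []
    scores: list[float] = []
    seen: set[str] = set()
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2:
            raise ParseError(path, lineno, "rank line needs 2 tab-separated fields")
        if lineno == 1 and not _is_number(fields[1]):
            continue  # header
        gene = normalize_gene(fields[0])
        if gene in seen:
            raise ParseError(path, lineno, f"duplicate gene {gene!r} in rank file")
        seen.add(gene)
        gene_ids.append(gene)
        scores.append(_float(fields[1], path, lineno, "rank score"))
    log.info("read %d ranked genes from %s", len(gene_ids), path)
    return RankedList(gene_ids=gene_ids, scores=scores)


# ---------------------------------------------------------------------------
# CLS

def read_class_file(path) -> ClassAssignment:
    """Read a GSEA CLS class file.

    Line 1: ``<n_samples> <n_classes> 1``; line 2: ``# label1 label2``;
    line 3: per-sample labels (names, or the 0/1 numeric variant which is
    mapped through the line-2 names).  Exactly two distinct classes are
    required.
    """
    lines = [l for l in _lines(path) if l.strip()]
    if len(lines) < 3:
        raise ParseError(path, None, "CLS file needs 3 non-empty lines")
    counts = lines[0].split()
    if len(counts) < 2:
        raise ParseError(path, 1, "CLS count line needs at least 2 numbers")
    n_samples = int(counts[0])
    n_classes = int(counts[1])
    if n_classes != 2:
        raise ParseError(path, 1, f"expected 2 classes, CLS declares {n_classes}")
    name_fields = lines[1].split()
    if not name_fields or name_fields[0] != "#":
        raise ParseError(path, 2, "CLS line 2 must start with '#'")
    class_names = name_fields[1:]
    if len(class_names) != 2:
        raise ParseError(path, 2, f"expected 2 class names, got {class_names}")
    raw_labels = lines[2].split()
    if len(raw_labels) != n_samples:
        raise ParseError(
            path, 3,
            f"CLS declares {n_samples} samples but line 3 has {len(raw_labels)}",
        )
    if all(_is_number(l) for l in raw_labels):
        # numeric variant: 0/1 indices into the declared class names
        labels = []
        for l in raw_labels:
            idx = int(float(l))
            if idx not in (0, 1):
                raise ParseError(path, 3, f"numeric class label {l!r} not 0/1")
            labels.append(class_names[idx])
    else:
        labels = raw_labels
    distinct = set(labels)
    if len(distinct) != 2:
        raise ParseError(
            path, 3, f"expected exactly 2 distinct labels, got {sorted(distinct)}"
        )
    sample_names = [f"sample_{i + 1}" for i in range(n_samples)]
    return ClassAssignment(sample_names=sample_names, labels=labels)


# ---------------------------------------------------------------------------
# Expression (GCT / TXT)

def read_expression_matrix(path) -> ExpressionMatrix:
    """Read an expression matrix in GCT or plain TXT form.

    GCT is detected by the ``#1.2`` version line and validated against its
    declared dimensions.  TXT is a header plus rows of
    ``name[\\tdescription]\\tvalues...``; whether a description column is
    present is detected by checking if column 2 of the first data row is
    numeric.  Missing cells are allowed (become NaN).
    """
    lines = _lines(path)
    if not lines:
        raise UnsupportedFileError(f"{path}: empty expression file")
    if lines[0].strip().startswith("#1.2"):
        return _read_gct(path, lines)
    return _read_expression_txt(path, lines)


def _parse_value(cell: str) -> float:
    cell = cell.strip()
    if cell == "" or cell.upper() in ("NA", "NAN", "NULL"):
        return math.nan
    return float(cell)


def _read_gct(path, lines: list[str]) -> ExpressionMatrix:
    if len(lines) < 3:
        raise ParseError(path, None, "GCT file needs version, dims and header lines")
    dims = lines[1].split()
    if len(dims) < 2:
        raise ParseError(path, 2, "GCT dimension line needs 2 numbers")
    n_genes, n_samples = int(dims[0]), int(dims[1])
    header = lines[2].split("\t")
    sample_names = [h.strip() for h in header[2:]]
    if len(sample_names) != n_samples:
        raise ParseError(
            path, 3,
            f"GCT declares {n_samples} samples but header has {len(sample_names)}",
        )
    body = [l for l in lines[3:] if l.strip()]
    if len(body) != n_genes:
        raise ParseError(
            path, None,
            f"GCT declares {n_genes} genes but body has {len(body)} rows",
        )
    return _assemble_expression(path, body, sample_names, has_description=True)


def _read_expression_txt(path, lines: list[str]) -> ExpressionMatrix:
    if len(lines) < 2:
        raise ParseError(path, None, "expression TXT needs a header and data rows")
    header = lines[0].split("\t")
    body = [l for l in lines[1:] if l.strip()]
    first = body[0].split("\t") if body else header
    # one or two leading annotation columns, detected on the first data row
    has_description = len(first) > 2 and not _is_number(first[1])
    n_annot = 2 if has_description else 1
    sample_names = [h.strip() for h in header[n_annot:]]
    return _assemble_expression(path, body, sample_names, has_description)


def _assemble_expression(
    path, body: list[str], sample_names: list[str], has_description: bool
) -> ExpressionMatrix:
    n_annot = 2 if has_description else 1
    gene_ids: list[str] = []
    descriptions: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(body, start=1):
        fields = line.split("\t")
        if len(fields) < n_annot:
            raise ParseError(path, lineno, "expression row too short")
        gene = normalize_gene(fields[0])
        if gene in gene_ids:
            raise ParseError(path, lineno, f"duplicate gene {gene!r} in expression")
        gene_ids.append(gene)
        descriptions.append(fields[1].strip() if has_description else "")
        values = fields[n_annot:]
        if len(values) != len(sample_names):
            raise ParseError(
                path, lineno,
                f"row has {len(values)} values for {len(sample_names)} samples",
            )
        try:
            rows.append([_parse_value(v) for v in values])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad expression value: {exc}") from None
    values = pd.DataFrame(rows, index=gene_ids, columns=sample_names, dtype=float)
    log.info(
        "read %dx%d expression matrix from %s", len(gene_ids), len(sample_names), path
    )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        gene_descriptions=descriptions,
        sample_names=sample_names,
        values=values,
    )


# ---------------------------------------------------------------------------
# DAVID / BiNGO / GREAT dialects

def read_tool_enrichments(
    path, dialect: str, great_pvalue: str = "hypergeometric"
) -> tuple[list[GeneSet], list[EnrichmentResult]]:
    """Read a DAVID chart, BiNGO table or GREAT export.

    These tools embed the member genes of each term in the result file, so
    both the gene sets and the enrichment records come from the single
    file and no separate GMT is needed.  Column mappings:

    - ``david``: Term -> name, PValue -> p, Benjamini -> q, Genes -> members
      (comma-separated).
    - ``bingo``: GO-ID -> name (zero-padded to ``GO:NNNNNNN``), p-value -> p,
      corr p-value -> q, Description -> description, last column -> members
      (pipe-separated).
    - ``great``: the term identifier/name columns -> name, the chosen
      statistic's raw p (``great_pvalue`` = ``"hypergeometric"`` or
      ``"binomial"``) -> p, its FDR column -> q, Genes -> members.
    """
    dialect = dialect.lower()
    if dialect == "david":
        return _read_david(path)
    if dialect == "bingo":
        return _read_bingo(path)
    if dialect == "great":
        return _read_great(path, great_pvalue)
    raise ValueError(f"unknown tool dialect {dialect!r}")


def _header_index(header: list[str], *aliases: str) -> Optional[int]:
    canon = [_canon_header(h) for h in header]
    for a in aliases:
        if a in canon:
            return canon.index(a)
    return None


def _read_david(path):
    lines = [l for l in _lines(path) if l.strip()]
    if not lines:
        raise UnsupportedFileError(f"{path}: empty DAVID chart")
    header = lines[0].split("\t")
    i_term = _header_index(header, "term")
    i_p = _header_index(header, "pvalue")
    i_q = _header_index(header, "benjamini")
    i_genes = _header_index(header, "genes")
    if i_term is None or i_p is None or i_genes is None:
        raise UnsupportedFileError(
            f"{path}: not a DAVID chart (needs Term, PValue and Genes columns)"
        )
    genesets: list[GeneSet] = []
    results: list[EnrichmentResult] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        term = fields[i_term].strip()
        # DAVID terms look like "GO:0000122~negative regulation of ..."
        name, _, description = term.partition("~")
        description = description or name
        genes = [g for g in fields[i_genes].split(",") if g.strip()]
        if not genes:
            raise ParseError(path, lineno, f"DAVID term {name!r} has no genes")
        pvalue = _float(fields[i_p], path, lineno, "p-value")
        qvalue = None
        if i_q is not None and i_q < len(fields) and fields[i_q].strip():
            qvalue = _float(fields[i_q], path, lineno, "Benjamini q")
        genesets.append(GeneSet.from_genes(name, description, genes))
        results.append(
            EnrichmentResult(
                set_name=name,
                description=description,
                pvalue=pvalue,
                qvalue=qvalue,
                source_dialect="david",
            )
        )
    log.info("read %d DAVID terms from %s", len(results), path)
    return genesets, results


def _read_bingo(path):
    lines = _lines(path)
    # BiNGO prefixes the table with free-form description lines; find header
    header_idx = None
    for i, line in enumerate(lines):
        if _canon_header(line.split("\t")[0]) == "goid":
            header_idx = i
            break
    if header_idx is None:
        raise UnsupportedFileError(f"{path}: not a BiNGO table (no GO-ID header)")
    header = lines[header_idx].split("\t")
    i_id = _header_index(header, "goid")
    i_p = _header_index(header, "pvalue")
    i_q = _header_index(header, "corrpvalue", "correctedpvalue")
    i_desc = _header_index(header, "description")
    i_genes = len(header) - 1  # members are always the last column
    genesets: list[GeneSet] = []
    results: list[EnrichmentResult] = []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        raw_id = fields[i_id].strip()
        name = f"GO:{int(raw_id):07d}" if _is_number(raw_id) else raw_id
        description = fields[i_desc].strip() if i_desc is not None else name
        genes = [g for g in fields[i_genes].split("|") if g.strip()]
        if not genes:
            raise ParseError(path, lineno, f"BiNGO term {name!r} has no genes")
        pvalue = _float(fields[i_p], path, lineno, "p-value")
        qvalue = None
        if i_q is not None and fields[i_q].strip():
            qvalue = _float(fields[i_q], path, lineno, "corrected p")
        genesets.append(GeneSet.from_genes(name, description, genes))
        results.append(
            EnrichmentResult(
                set_name=name,
                description=description,
                pvalue=pvalue,
                qvalue=qvalue,
                source_dialect="bingo",
            )
        )
    log.info("read %d BiNGO terms from %s", len(results), path)
    return genesets, results


def _read_great(path, great_pvalue: str):
    if great_pvalue not in ("hypergeometric", "binomial"):
        raise ValueError(
            f"great_pvalue must be 'hypergeometric' or 'binomial', got {great_pvalue!r}"
        )
    lines = [l for l in _lines(path) if l.strip() and not l.startswith("#")]
    if not lines:
        raise UnsupportedFileError(f"{path}: empty GREAT export")
    header = lines[0].split("\t")
    i_name = _header_index(header, "termname", "desc", "id")
    i_genes = _header_index(header, "genes", "geneshits")
    if great_pvalue == "hypergeometric":
        i_p = _header_index(header, "hyperrawpvalue", "hyperpvalue")
        i_q = _header_index(header, "hyperfdrqval", "hyperfdrqvalue")
    else:
        i_p = _header_index(header, "binomrawpvalue", "binompvalue")
        i_q = _header_index(header, "binomfdrqval", "binomfdrqvalue")
    if i_name is None or i_p is None or i_genes is None:
        raise UnsupportedFileError(
            f"{path}: not a GREAT export (needs term name, {great_pvalue} p "
            "and Genes columns)"
        )
    genesets: list[GeneSet] = []
    results: list[EnrichmentResult] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        name = fields[i_name].strip()
        genes = [g for g in re.split(r"[,|]", fields[i_genes]) if g.strip()]
        if not genes:
            raise ParseError(path, lineno, f"GREAT term {name!r} has no genes")
        pvalue = _float(fields[i_p], path, lineno, "p-value")
        qvalue = None
        if i_q is not None and i_q < len(fields) and fields[i_q].strip():
            qvalue = _float(fields[i_q], path, lineno, "FDR q")
        genesets.append(GeneSet.from_genes(name, name, genes))
        results.append(
            EnrichmentResult(
                set_name=name,
                description=name,
                pvalue=pvalue,
                qvalue=qvalue,
                source_dialect="great",
            )
        )
    log.info("read %d GREAT terms from %s", len(results), path)
    return genesets, results
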