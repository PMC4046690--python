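"""Readers and writers for the pipeline's external file formats.

Conventions
-----------
Gene coordinates are 1-based inclusive (GTF convention); peak coordinates are
0-based half-open (BED convention).  All cross-format comparisons convert to
0-based half-open internally, once, at the point of use.

The transcription start site (TSS) of a plus-strand gene is its annotated
``start``; for a minus-strand gene it is the annotated ``end``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .interval_ops import PeakSetCollection

__all__ = [
    "GeneRecord",
    "PeakInterval",
    "ExpressionMatrix",
    "ParalogTable",
    "ParseError",
    "ValidationError",
    "make_gene",
    "read_gene_table",
    "write_gene_table",
    "read_peaks",
    "read_expression",
    "read_paralog_table",
    "read_go_annotation",
    "read_term_depths",
    "read_upstream_fasta",
    "write_upstream_fasta",
    "write_bed",
]

GO_ID_RE = re.compile(r"^GO:\d{7}$")
_GTF_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a data-model invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with a strand-aware TSS (1-based inclusive coords)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        expected = self.start if self.strand == "+" else self.end
        if self.tss != expected:
            raise ValidationError(
                f"{self.gene_id}: tss {self.tss} inconsistent with strand"
            )


def make_gene(gene_id: str, chrom: str, strand: str, start: int, end: int) -> GeneRecord:
    """Build a :class:`GeneRecord`, deriving the TSS from the strand."""
    tss = start if strand == "+" else end
    return GeneRecord(gene_id, chrom, strand, int(start), int(end), int(tss))


@dataclass(frozen=True)
class PeakInterval:
    """One ChIP-seq peak: 0-based half-open, tagged with its cell type."""

    chrom: str
    start: int
    end: int
    cell_type: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"{self.cell_type}:{self.chrom}: peak start {self.start} >= end {self.end}"
            )


class ExpressionMatrix:
    """Genes x tissues expression signals with validated invariants."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if df.isna().any().any():
            raise ValidationError("expression matrix has missing cells")
        if (df.to_numpy() < 0).any():
            raise ValidationError("expression signals must be non-negative")
        self.df = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.df.columns)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.df.index

    def vector(self, gene_id: str) -> np.ndarray:
        return self.df.loc[gene_id].to_numpy()


class ParalogTable:
    """Unordered paralog pairs with synonymous divergence and ancestor labels."""

    def __init__(self, rows: Iterable[tuple[str, str, float | None, str]]):
        self._rows: dict[frozenset, tuple[float | None, str]] = {}
        for gene_a, gene_b, ds, ancestor in rows:
            if ds is not None and not np.isnan(ds) and ds < 0:
                raise ValidationError(f"negative d_S for pair ({gene_a},{gene_b})")
            key = frozenset((gene_a, gene_b))
            if key in self._rows:
                raise ValidationError(f"duplicate paralog pair ({gene_a},{gene_b})")
            self._rows[key] = (ds, ancestor)

    def __len__(self) -> int:
        return len(self._rows)

    def contains(self, gene_a: str, gene_b: str) -> bool:
        return frozenset((gene_a, gene_b)) in self._rows

    def lookup(self, gene_a: str, gene_b: str) -> tuple[float | None, str] | None:
        return self._rows.get(frozenset((gene_a, gene_b)))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_gene_table(path: str | Path, format: str | None = None) -> list[GeneRecord]:
    """Read a gene annotation (TSV or Ensembl-dialect GTF) into sorted records.

    TSV columns: gene_id, chrom, strand, start, end (an optional header line
    beginning with ``gene_id`` is skipped).  From a GTF only ``gene`` features
    are used and the ``gene_id`` attribute is required.
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "tsv"
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                if format == "gtf":
                    fields = line.split("\t")
                    if len(fields) < 9:
                        raise ParseError("fewer than 9 GTF columns")
                    if fields[2] != "gene":
                        continue
                    m = _GTF_GENE_ID_RE.search(fields[8])
                    if m is None:
                        raise ParseError("missing gene_id attribute")
                    genes.append(
                        make_gene(m.group(1), fields[0], fields[6],
                                  int(fields[3]), int(fields[4]))
                    )
                else:
                    fields = _split(line)
                    if fields[0] == "gene_id":  # header
                        continue
                    if len(fields) < 5:
                        raise ParseError("expected 5 columns")
                    genes.append(
                        make_gene(fields[0], fields[1], fields[2],
                                  int(fields[3]), int(fields[4]))
                    )
            except ValidationError:
                raise
            except (ParseError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\n")


def read_peaks(paths: Sequence[str | Path],
               labels: Sequence[str] | None = None) -> PeakSetCollection:
    """Read one BED/broadPeak file per cell type (columns 1-3 only)."""
    if not paths:
        raise ValidationError("at least one peak file is required")
    if labels is None:
        labels = [Path(p).stem for p in paths]
    per_cell: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for label, path in zip(labels, paths):
        intervals: dict[str, list[tuple[int, int]]] = {}
        n = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = _split(line)
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if end <= start:
                    raise ValidationError(f"{path}:{lineno}: end <= start")
                intervals.setdefault(chrom, []).append((start, end))
                n += 1
        if n == 0:
            warnings.warn(f"peak file {path} is empty", stacklevel=2)
        for ivs in intervals.values():
            ivs.sort()
        per_cell[label] = intervals
    return PeakSetCollection(per_cell)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-tissues TSV with a tissue-id header row."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t)
                              for t in df.dtypes]]
    if len(non_numeric):
        raise ParseError(f"{path}: non-numeric column(s) {list(non_numeric)}")
    return ExpressionMatrix(df)


def read_paralog_table(path: str | Path) -> ParalogTable:
    """Read the paralog-pair table: gene_a, gene_b, d_S (may be NA), ancestor."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = _split(line)
            if fields[0] == "gene_a":  # header
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            ds_str = fields[2]
            ds = None if ds_str in ("", "NA", "nan") else float(ds_str)
            rows.append((fields[0], fields[1], ds, fields[3]))
    return ParalogTable(rows)


def read_go_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column gene -> GO-term TSV into a multi-valued mapping."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = _split(line)
            if fields[0] == "gene_id":
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            gene, term = fields[0], fields[1]
            if not GO_ID_RE.match(term):
                raise ValidationError(f"{path}:{lineno}: malformed GO id {term!r}")
            mapping.setdefault(gene, set()).add(term)
    return mapping


def read_term_depths(path: str | Path) -> dict[str, int]:
    """Read a per-term ontology-depth table (term, depth)."""
    depths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = _split(line)
            if fields[0] == "term":
                continue
            if not GO_ID_RE.match(fields[0]):
                raise ValidationError(f"{path}:{lineno}: malformed GO id")
            depths[fields[0]] = int(fields[1])
    return depths


def read_upstream_fasta(path: str | Path) -> dict[str, str]:
    """Read per-gene upstream sequences (FASTA keyed by gene id)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_upstream_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=gid, description="") for gid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bed(intervals: Mapping[str, Sequence[tuple[int, int]]],
              path: str | Path) -> None:
    """Write a per-chromosome interval dict as BED3 (sorted)."""
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start, end in intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")
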