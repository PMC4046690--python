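"""Adjacent gene-pair construction, relation labelling and orientation classes.

Adjacency is genome-order adjacency on each chromosome, regardless of strand.
A pair is *paralogous* iff its unordered id pair appears in the paralog table
(only directly adjacent paralogs, i.e. tandem neighbours, qualify).
Orientation follows the strand configuration of (left, right):

* ``-``/``+``  -> head_to_head (divergent TSSs face each other)
* same strand  -> head_to_tail (co-directional)
* ``+``/``-``  -> tail_to_tail (convergent)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import ExpressionMatrix, GeneRecord, ParalogTable, ValidationError
from .features import CpGProfile

__all__ = ["AdjacentPair", "build_adjacent_pairs", "classify_orientation",
           "filter_analyzable"]

HEAD_TO_HEAD = "head_to_head"
HEAD_TO_TAIL = "head_to_tail"
TAIL_TO_TAIL = "tail_to_tail"


@dataclass(frozen=True)
class AdjacentPair:
    """Two neighbouring genes on one chromosome (left.start <= right.start)."""

    left: GeneRecord
    right: GeneRecord
    relation: str  # {"paralog", "non_paralog"}
    orientation: str
    overlapping_bodies: bool = False

    @property
    def pair_id(self) -> str:
        return f"{self.left.gene_id}|{self.right.gene_id}"


def classify_orientation(left_strand: str, right_strand: str) -> str:
    """Orientation class of an adjacent pair from its two strands."""
    for s in (left_strand, right_strand):
        if s not in ("+", "-"):
            raise ValidationError(f"unknown strand symbol {s!r}")
    if left_strand == right_strand:
        return HEAD_TO_TAIL
    return HEAD_TO_HEAD if left_strand == "-" else TAIL_TO_TAIL


def build_adjacent_pairs(genes: Sequence[GeneRecord],
                         paralogs: ParalogTable) -> list[AdjacentPair]:
    """Pair each consecutive gene couple per chromosome and label the relation.

    ``genes`` must already be sorted by (chrom, start) as produced by
    :func:`~ctcf_divergence.genome_io.read_gene_table`.  Pairs whose gene
    bodies overlap are retained but flagged.
    """
    pairs: list[AdjacentPair] = []
    for left, right in zip(genes, genes[1:]):
        if left.chrom != right.chrom:
            continue
        relation = ("paralog" if paralogs.contains(left.gene_id, right.gene_id)
                    else "non_paralog")
        pairs.append(AdjacentPair(
            left=left,
            right=right,
            relation=relation,
            orientation=classify_orientation(left.strand, right.strand),
            overlapping_bodies=right.start <= left.end,
        ))
    return pairs


def _detectable(x: np.ndarray) -> bool:
    # "detectable expression" = signal > 0 in at least one tissue
    return bool((x > 0).any())


def filter_analyzable(pairs: Sequence[AdjacentPair],
                      expression: ExpressionMatrix,
                      cpg: Mapping[str, CpGProfile],
                      ) -> tuple[list[AdjacentPair], dict[str, int]]:
    """Keep pairs where both genes are expressed and have estimable CpG_O/E.

    Returns the retained pairs and a per-reason drop count for the run
    manifest (a pair is attributed to its first failing check).
    """
    kept: list[AdjacentPair] = []
    drops = {"missing_expression": 0, "undetectable_expression": 0,
             "missing_cpg": 0, "inestimable_cpg": 0}
    for pair in pairs:
        reason = None
        for gene in (pair.left, pair.right):
            gid = gene.gene_id
            if gid not in expression:
                reason = "missing_expression"
                break
            if not _detectable(expression.vector(gid)):
                reason = "undetectable_expression"
                break
            if gid not in cpg:
                reason = "missing_cpg"
                break
            if not cpg[gid].estimable:
                reason = "inestimable_cpg"
                break
        if reason is None:
            kept.append(pair)
        else:
            drops[reason] += 1
    return kept, drops
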