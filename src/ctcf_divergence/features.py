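"""Per-pair genomic covariates.

For every adjacent gene pair the analysis uses three genomic properties:

* ``d`` — intergenic distance, nucleotides between the two TSSs;
* ``#CTCF`` — number of consensus CTCF-binding sites in the inter-TSS window,
  in two dialects (``overlapping`` = intersection across cell types,
  ``joint`` = union), plus the density ``#CTCF/d``;
* ``ΔCpG_O/E`` — absolute difference in the CpG observed/expected ratio of the
  500-nt windows upstream of the two TSSs, a proxy for germline DNA
  methylation (methylated CpGs deaminate, depleting CpG dinucleotides).

CpG_O/E = P_CpG / (P_C x P_G) where P_CpG is the frequency of CpG
dinucleotides over the L-1 overlapping dinucleotide positions and P_C, P_G
are mononucleotide frequencies over the L unambiguous bases.  Ambiguity
characters (N) are excluded from L and dinucleotides spanning an N are
skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

from .interval_ops import PeakSetCollection, count_in_window

if TYPE_CHECKING:  # pragma: no cover
    from .genome_io import GeneRecord
    from .pairing import AdjacentPair

__all__ = ["CpGProfile", "cpg_oe", "upstream_window", "intergenic_distance",
           "delta_cpg", "ctcf_counts", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = [
    "pair_id", "left_id", "right_id", "relation", "orientation",
    "d", "n_ctcf_overlap", "n_ctcf_joint", "ctcf_density", "delta_cpg",
    "expd_1r", "expd_euc", "ds", "t_phy",
]


@dataclass(frozen=True)
class CpGProfile:
    """Mono- and dinucleotide frequencies of one upstream window."""

    p_cpg: float
    p_c: float
    p_g: float
    cpg_oe: float
    estimable: bool


_NOT_ESTIMABLE = CpGProfile(math.nan, math.nan, math.nan, math.nan, False)


def cpg_oe(sequence: str) -> CpGProfile:
    """CpG observed/expected ratio of a nucleotide string (case-insensitive)."""
    seq = sequence.upper()
    n_c = n_g = n_cpg = length = 0
    prev = "N"
    for base in seq:
        if base == "N":
            prev = "N"
            continue
        length += 1
        if base == "C":
            n_c += 1
        elif base == "G":
            n_g += 1
            if prev == "C":
                n_cpg += 1
        prev = base
    if length < 2 or n_c == 0 or n_g == 0:
        return _NOT_ESTIMABLE
    p_cpg = n_cpg / (length - 1)
    p_c = n_c / length
    p_g = n_g / length
    return CpGProfile(p_cpg, p_c, p_g, p_cpg / (p_c * p_g), True)


def upstream_window(gene: "GeneRecord", flank: int = 500) -> tuple[str, int, int]:
    """0-based half-open window of ``flank`` bp upstream of the TSS.

    Plus strand: 1-based bases [tss-flank, tss-1]; minus strand:
    [tss+1, tss+flank].  Clipped at the chromosome origin.
    """
    if gene.strand == "+":
        lo, hi = gene.tss - flank - 1, gene.tss - 1
    else:
        lo, hi = gene.tss, gene.tss + flank
    return gene.chrom, max(0, lo), max(0, hi)


def intergenic_distance(pair: "AdjacentPair") -> int:
    """TSS-to-TSS distance ``d`` in nucleotides."""
    if pair.left.chrom != pair.right.chrom:
        raise ValueError(f"{pair.pair_id}: genes on different chromosomes")
    return abs(pair.left.tss - pair.right.tss)


def delta_cpg(pair: "AdjacentPair", cpg_by_gene: Mapping[str, CpGProfile]) -> float:
    """ΔCpG_O/E: absolute CpG_O/E difference between the two genes."""
    left = cpg_by_gene[pair.left.gene_id]
    right = cpg_by_gene[pair.right.gene_id]
    if not (left.estimable and right.estimable):
        raise ValueError(f"{pair.pair_id}: CpG_O/E not estimable")
    return abs(left.cpg_oe - right.cpg_oe)


def inter_tss_window(pair: "AdjacentPair") -> tuple[str, int, int]:
    """The #CTCF counting region: 0-based half-open [min(tss)-1, max(tss)-1).

    The 1-based half-open inter-TSS span [min(tss), max(tss)) covers exactly
    ``d`` bases; this is its 0-based image.
    """
    lo = min(pair.left.tss, pair.right.tss)
    hi = max(pair.left.tss, pair.right.tss)
    return pair.left.chrom, lo - 1, hi - 1


def ctcf_counts(pair: "AdjacentPair", peaks: PeakSetCollection,
                ) -> tuple[int, int, float]:
    """(#CTCF overlapping, #CTCF joint, #CTCF/d) for one pair.

    Density uses the overlapping dialect; a zero-distance pair yields density
    0.0 when it has no sites and NaN otherwise (flagged upstream).
    """
    chrom, lo, hi = inter_tss_window(pair)
    n_overlap = count_in_window(peaks.overlapping, chrom, lo, hi)
    n_joint = count_in_window(peaks.joint, chrom, lo, hi)
    d = hi - lo
    if d == 0:
        density = 0.0 if n_overlap == 0 else math.nan
    else:
        density = n_overlap / d
    return n_overlap, n_joint, density
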