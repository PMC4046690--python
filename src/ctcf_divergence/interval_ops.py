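"""Exact interval-set algebra for CTCF consensus construction.

Intervals are 0-based half-open ``(start, end)`` tuples grouped per chromosome
in a plain ``dict[str, list[tuple[int, int]]]``.  Two consensus dialects are
derived from the per-cell-type ChIP-seq peak sets:

* ``overlapping`` — base-wise intersection across all cell types, re-segmented
  into maximal intervals (binding regions present in every examined cell type);
* ``joint`` — merged union across all cell types.

Touching intervals ([0,5), [5,10)) merge in unions.  Window counting is by
>=1 bp overlap, not containment.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Mapping, Sequence

__all__ = [
    "IntervalDict",
    "merge_intervals",
    "union_all",
    "intersect_all",
    "count_in_window",
    "covered_bases",
    "PeakSetCollection",
]

IntervalDict = dict[str, list[tuple[int, int]]]


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge a flat interval list; touching intervals coalesce."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            if end > out[-1][1]:
                out[-1] = (out[-1][0], end)
        else:
            out.append((start, end))
    return out


def _intersect_two(a: Sequence[tuple[int, int]],
                   b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersect two sorted disjoint interval lists by linear sweep."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def union_all(sets: Sequence[IntervalDict]) -> IntervalDict:
    """Merged cover of all input sets (the 'joint' consensus)."""
    pooled: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        for chrom, ivs in s.items():
            pooled.setdefault(chrom, []).extend(ivs)
    return {chrom: merge_intervals(ivs) for chrom, ivs in pooled.items() if ivs}


def intersect_all(sets: Sequence[IntervalDict]) -> IntervalDict:
    """Maximal intervals covered in *every* input set (the 'overlapping' consensus)."""
    if not sets:
        raise ValueError("intersect_all requires at least one interval set")
    # merge each set first so intersection is base-wise coverage intersection
    merged = [union_all([s]) for s in sets]
    chroms = set(merged[0])
    for s in merged[1:]:
        chroms &= set(s)
    out: IntervalDict = {}
    for chrom in chroms:
        acc = merged[0][chrom]
        for s in merged[1:]:
            acc = _intersect_two(acc, s[chrom])
            if not acc:
                break
        if acc:
            out[chrom] = acc
    return out


def count_in_window(consensus: Mapping[str, Sequence[tuple[int, int]]],
                    chrom: str, lo: int, hi: int, *,
                    lenient_zero: bool = True) -> int:
    """Number of consensus intervals overlapping window [lo, hi) by >=1 bp."""
    if lo > hi or (lo == hi and not lenient_zero):
        raise ValueError(f"malformed window [{lo}, {hi})")
    if lo == hi:
        return 0
    ivs = consensus.get(chrom, [])
    starts = [s for s, _ in ivs]
    n = 0
    # first candidate: last interval starting before hi; scan left while end > lo
    idx = bisect_right(starts, hi - 1)
    for k in range(idx - 1, -1, -1):
        if ivs[k][1] > lo:
            n += 1
        else:
            break
    return n


def covered_bases(intervals: Mapping[str, Sequence[tuple[int, int]]]) -> dict[str, set[int]]:
    """Explicit per-base coverage; intended for small inputs and oracle checks."""
    return {chrom: {b for s, e in ivs for b in range(s, e)}
            for chrom, ivs in intervals.items()}


class PeakSetCollection:
    """Per-cell-type CTCF peak sets plus lazily derived consensus dialects."""

    def __init__(self, per_cell_type: Mapping[str, IntervalDict]):
        if not per_cell_type:
            raise ValueError("PeakSetCollection requires >=1 cell type")
        self.per_cell_type = {
            cell: {chrom: sorted(ivs) for chrom, ivs in sets.items()}
            for cell, sets in per_cell_type.items()
        }
        self._overlapping: IntervalDict | None = None
        self._joint: IntervalDict | None = None

    @property
    def cell_types(self) -> list[str]:
        return list(self.per_cell_type)

    @property
    def overlapping(self) -> IntervalDict:
        if self._overlapping is None:
            self._overlapping = intersect_all(list(self.per_cell_type.values()))
        return self._overlapping

    @property
    def joint(self) -> IntervalDict:
        if self._joint is None:
            self._joint = union_all(list(self.per_cell_type.values()))
        return self._joint

    def consensus(self, dialect: str) -> IntervalDict:
        if dialect == "overlapping":
            return self.overlapping
        if dialect == "joint":
            return self.joint
        raise ValueError(f"unknown consensus dialect {dialect!r}")
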