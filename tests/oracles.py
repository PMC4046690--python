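"""Independent brute-force oracles used to verify the fast implementations.

These deliberately avoid the code paths (and, where feasible, the libraries)
they check: interval algebra by explicit per-base sets, Spearman and partial
Spearman by hand-rolled ranking plus normal-equation regression, Fisher's
exact test by exhaustive enumeration of all tables with the observed margins.
"""

from __future__ import annotations

import math

import numpy as np


def segment_bases(bases: set[int]) -> list[tuple[int, int]]:
    """Re-segment an explicit base set into maximal half-open intervals."""
    out = []
    for b in sorted(bases):
        if out and b == out[-1][1]:
            out[-1] = (out[-1][0], b + 1)
        else:
            out.append((b, b + 1))
    return [tuple(iv) for iv in out]


def bases_of(intervals) -> set[int]:
    return {b for s, e in intervals for b in range(s, e)}


def oracle_union(sets: list[dict]) -> dict:
    chroms = {c for s in sets for c in s}
    out = {}
    for chrom in sorted(chroms):
        bases = set()
        for s in sets:
            bases |= bases_of(s.get(chrom, []))
        if bases:
            out[chrom] = segment_bases(bases)
    return out


def oracle_intersection(sets: list[dict]) -> dict:
    chroms = {c for s in sets for c in s}
    out = {}
    for chrom in sorted(chroms):
        bases = bases_of(sets[0].get(chrom, []))
        for s in sets[1:]:
            bases &= bases_of(s.get(chrom, []))
        if bases:
            out[chrom] = segment_bases(bases)
    return out


def oracle_count(intervals, lo: int, hi: int) -> int:
    return sum(1 for s, e in intervals if s < hi and e > lo)


def oracle_ranks(v) -> np.ndarray:
    """Average (fractional) ranks computed by explicit tie-group averaging."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / math.sqrt((a * a).sum() * (b * b).sum()))


def oracle_spearman(x, y) -> float:
    return _corr(oracle_ranks(x), oracle_ranks(y))


def oracle_partial_spearman(x, y, controls) -> float:
    """Rank everything, regress x and y ranks on control ranks via normal
    equations, correlate the residuals."""
    rx = oracle_ranks(x)
    ry = oracle_ranks(y)
    if not controls:
        return _corr(rx, ry)
    z = np.column_stack([np.ones(len(rx))] + [oracle_ranks(c) for c in controls])
    proj = z @ np.linalg.inv(z.T @ z) @ z.T
    return _corr(rx - proj @ rx, ry - proj @ ry)


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k: int) -> float:
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(p for k in range(lo, hi + 1)
               if (p := pmf(k)) <= p_obs * (1 + 1e-9))
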