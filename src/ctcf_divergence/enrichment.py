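"""Top-quartile #CTCF/d split and GO-term enrichment testing.

Gene pairs in the top quartile of CTCF-binding-site density (#CTCF/d) are
compared against the bottom three quartiles.  For each GO term a 2x2 table
(term/non-term x top/rest) over the member genes of the stratum's pairs is
tested with a two-sided Fisher exact test; p-values are Bonferroni-corrected
within the stratum's family of tests.  Paralogous and non-paralogous pairs
form separate families, and a term is *specifically* enriched in one stratum
when it is significant there and not significant in the other.

GO "level" (ontology depth) is an explicit per-term attribute of the input;
:func:`term_depths_from_obo` computes min-depths from an OBO file when no
depth table is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

__all__ = ["EnrichmentRecord", "quartile_split", "genes_of", "fisher_term_test",
           "run_enrichment", "select_subset_pairs", "term_depths_from_obo"]


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    direction: str          # {"enriched", "depleted"}
    a: int                  # term & top
    b: int                  # term & rest
    c: int                  # non-term & top
    d_cell: int             # non-term & rest
    odds_ratio: float
    p_raw: float
    p_bonf: float
    n_tests: int
    stratum: str = "all"
    specific: bool = False


def quartile_split(features: pd.DataFrame,
                   density_col: str = "ctcf_density",
                   id_col: str = "pair_id",
                   ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Split pairs into the top ceil(n/4) by density and the rest.

    Ties spanning the cut are broken deterministically by stable pair-id
    order; the ids of tie-affected pairs are returned for logging.
    """
    df = features.dropna(subset=[density_col])
    n = len(df)
    if n < 4:
        raise ValueError(f"quartile split needs >= 4 pairs, got {n}")
    k = math.ceil(n / 4)
    ordered = df.sort_values([density_col, id_col],
                             ascending=[False, True], kind="mergesort")
    top = ordered.iloc[:k]
    rest = ordered.iloc[k:]
    cut = top[density_col].iloc[-1]
    tie_notes: list[str] = []
    if (rest[density_col] == cut).any():
        tied = ordered.loc[ordered[density_col] == cut, id_col].tolist()
        tie_notes = tied
    return top, rest, tie_notes


def genes_of(pairs: pd.DataFrame, left_col: str = "left_id",
             right_col: str = "right_id") -> set[str]:
    """Deduplicated union of member gene ids of a pair set."""
    return set(pairs[left_col]) | set(pairs[right_col])


def fisher_term_test(term_genes: set[str], top_genes: set[str],
                     universe: set[str]) -> tuple[int, int, int, int, float, float]:
    """(a, b, c, d, odds_ratio, p) for one term's 2x2 top/rest table.

    The p-value is the two-sided Fisher exact probability from the
    hypergeometric distribution; the odds ratio gets a Haldane 0.5 correction
    for display only when a zero cell exists (p unaffected).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not top_genes <= universe:
        raise ValueError("top genes must be a subset of the universe")
    term_in = term_genes & universe
    a = len(term_in & top_genes)
    b = len(term_in) - a
    c = len(top_genes) - a
    d = len(universe) - a - b - c
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return a, b, c, d, float(odds), float(p)


def run_enrichment(pairs: pd.DataFrame, go_map: Mapping[str, set[str]],
                   term_depths: Mapping[str, int] | None = None,
                   level: int = 4, alpha: float = 0.05,
                   stratum: str = "all",
                   density_col: str = "ctcf_density",
                   ) -> list[EnrichmentRecord]:
    """Enrichment/depletion of every tested GO term in one pair stratum.

    The gene universe is all member genes of the stratum's pairs; terms are
    restricted to the requested ontology depth when a depth table is given.
    ``n_tests`` (the Bonferroni factor) is the number of terms tested in this
    stratum.
    """
    top, rest, _ = quartile_split(pairs, density_col=density_col)
    top_genes = genes_of(top)
    universe = genes_of(pairs)
    term_to_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in go_map.get(gene, ()):
            term_to_genes.setdefault(term, set()).add(gene)
    if term_depths is not None:
        term_to_genes = {t: g for t, g in term_to_genes.items()
                         if term_depths.get(t) == level}
    if not term_to_genes:
        warnings.warn(f"no GO terms at level {level} in stratum {stratum}",
                      stacklevel=2)
        return []
    n_tests = len(term_to_genes)
    records = []
    for term in sorted(term_to_genes):
        a, b, c, d, odds, p = fisher_term_test(term_to_genes[term], top_genes,
                                               universe)
        records.append(EnrichmentRecord(
            term=term,
            direction="enriched" if odds > 1 else "depleted",
            a=a, b=b, c=c, d_cell=d,
            odds_ratio=odds, p_raw=p,
            p_bonf=min(1.0, p * n_tests),
            n_tests=n_tests, stratum=stratum))
    return records


def mark_specific(records_a: list[EnrichmentRecord],
                  records_b: list[EnrichmentRecord],
                  alpha: float = 0.05,
                  ) -> tuple[list[EnrichmentRecord], list[EnrichmentRecord]]:
    """Flag terms significant in one stratum and not significant in the other."""
    def sig_terms(records: Iterable[EnrichmentRecord]) -> set[str]:
        return {r.term for r in records if r.p_bonf < alpha}

    sig_a, sig_b = sig_terms(records_a), sig_terms(records_b)

    def flag(records: list[EnrichmentRecord], own: set[str], other: set[str]):
        return [EnrichmentRecord(**{**r.__dict__,
                                    "specific": r.term in own - other})
                for r in records]

    return flag(records_a, sig_a, sig_b), flag(records_b, sig_b, sig_a)


def select_subset_pairs(records: Sequence[EnrichmentRecord],
                        pairs: pd.DataFrame,
                        go_map: Mapping[str, set[str]],
                        alpha: float = 0.05,
                        mode: str = "specific") -> pd.DataFrame:
    """Pairs in which >= 1 member carries >= 1 selected enriched term.

    ``mode='specific'`` restricts to terms enriched in this stratum's family
    and not significant in the other stratum (the cross-stratum contrast);
    ``mode='all'`` uses every enriched significant term.
    """
    if mode not in ("specific", "all"):
        raise ValueError(f"unknown subset mode {mode!r}")
    selected = {r.term for r in records
                if r.direction == "enriched" and r.p_bonf < alpha
                and (r.specific or mode == "all")}
    if not selected:
        return pairs.iloc[0:0]
    keep = [
        bool((go_map.get(left, set()) | go_map.get(right, set())) & selected)
        for left, right in zip(pairs["left_id"], pairs["right_id"])
    ]
    return pairs[keep]


def term_depths_from_obo(path: str) -> dict[str, int]:
    """Min-depth of every term in an OBO file (roots at depth 0, via is_a).

    Utility for real GO releases; requires the optional ``obonet`` dependency.
    """
    import networkx as nx
    import obonet

    graph = obonet.read_obo(path)
    # obonet edges point child -> parent; reverse for root-down BFS
    rev = graph.reverse(copy=False)
    roots = [n for n in graph if graph.out_degree(n) == 0]
    depths: dict[str, int] = {}
    for root in roots:
        for node, depth in nx.single_source_shortest_path_length(rev, root).items():
            if node not in depths or depth < depths[node]:
                depths[node] = depth
    return depths


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term": r.term, "stratum": r.stratum, "direction": r.direction,
        "a": r.a, "b": r.b, "c": r.c, "d": r.d_cell,
        "odds_ratio": r.odds_ratio, "p_raw": r.p_raw, "p_bonf": r.p_bonf,
        "n_tests": r.n_tests, "specific": r.specific,
    } for r in records])
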