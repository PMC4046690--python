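import numpy as np
import pandas as pd
import pytest

from ctcf_divergence.enrichment import (fisher_term_test, genes_of,
                                        mark_specific, quartile_split,
                                        run_enrichment, select_subset_pairs)

from .oracles import oracle_fisher_two_sided


def _pairs(densities, prefix="p"):
    n = len(densities)
    return pd.DataFrame({
        "pair_id": [f"{prefix}{i:03d}" for i in range(n)],
        "left_id": [f"{prefix}{i:03d}L" for i in range(n)],
        "right_id": [f"{prefix}{i:03d}R" for i in range(n)],
        "ctcf_density": densities,
    })


class TestQuartileSplit:
    def test_four_pairs_top_is_max(self):
        top, rest, _ = quartile_split(_pairs([1.0, 2.0, 3.0, 4.0]))
        assert list(top.ctcf_density) == [4.0]
        assert sorted(rest.ctcf_density) == [1.0, 2.0, 3.0]

    def test_eight_distinct_gives_two(self):
        top, rest, _ = quartile_split(_pairs(list(map(float, range(8)))))
        assert len(top) == 2 and len(rest) == 6

    def test_ties_split_deterministically_and_logged(self):
        densities = [5.0, 3.0, 3.0, 3.0, 1.0, 0.5, 0.2, 0.1]
        df = _pairs(densities)
        top1, _, notes = quartile_split(df)
        top2, _, _ = quartile_split(df.sample(frac=1, random_state=4))
        assert list(top1.pair_id) == list(top2.pair_id)  # order-independent
        assert notes  # the tie spanning the cut is reported
        assert list(top1.pair_id) == ["p000", "p001"]  # stable id order

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            quartile_split(_pairs([1.0, 2.0, 3.0]))


class TestGenesOf:
    def test_disjoint_pairs(self):
        assert len(genes_of(_pairs([1.0, 2.0]))) == 4

    def test_shared_gene_deduplicated(self):
        df = pd.DataFrame({"left_id": ["a", "b"], "right_id": ["b", "c"]})
        assert genes_of(df) == {"a", "b", "c"}


class TestFisher:
    def test_perfect_balance(self):
        a, b, c, d, odds, p = fisher_term_test(
            set("abcdefghij"), set("abcdeklmno"),
            set("abcdefghijklmnopqrst"))
        assert (a, b, c, d) == (5, 5, 5, 5)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_extreme_table_enumerated(self):
        # (a=4, b=0, c=0, d=4): only a=0 and a=4 are as extreme -> p = 2/70
        universe = set("abcdefgh")
        a, b, c, d, odds, p = fisher_term_test(set("abcd"), set("abcd"),
                                               universe)
        assert (a, b, c, d) == (4, 0, 0, 4)
        assert p == pytest.approx(2 / 70, abs=1e-12)
        assert odds > 1  # Haldane-corrected display value

    def test_depleted_direction(self):
        universe = {f"g{i}" for i in range(20)}
        top = {f"g{i}" for i in range(5)}
        term = {f"g{i}" for i in range(5, 12)}  # absent from top
        *_, odds, p = fisher_term_test(term, top, universe)
        assert odds < 1

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(120):
            total = int(rng.integers(4, 41))
            cuts = sorted(rng.integers(0, total + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = total - a - b - c
            universe = {f"g{i}" for i in range(total)}
            genes = sorted(universe)
            term = set(genes[:a]) | set(genes[a + c:a + c + b])
            top = set(genes[:a + c])
            aa, bb, cc, dd, _, p = fisher_term_test(term, top, universe)
            assert (aa, bb, cc, dd) == (a, b, c, d)
            assert p == pytest.approx(oracle_fisher_two_sided(a, b, c, d),
                                      abs=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_term_test({"a"}, set(), set())


class TestRunEnrichment:
    def _planted(self, seed=22, n=120, factor=6.0):
        rng = np.random.default_rng(seed)
        df = _pairs(list(rng.random(n)))
        top, _, _ = quartile_split(df)
        high = genes_of(top)
        go = {}
        p0 = 0.1
        # sorted: keeps the rng draw order independent of set hashing
        for gene in sorted(genes_of(df)):
            terms = {t for t in ("GO:0000002", "GO:0000003")
                     if rng.random() < p0}
            if rng.random() < (min(1.0, factor * p0) if gene in high else p0):
                terms.add("GO:0000001")
            if terms:
                go[gene] = terms
        return df, go

    def test_planted_term_detected_others_not(self):
        df, go = self._planted()
        records = run_enrichment(df, go, alpha=0.05)
        by_term = {r.term: r for r in records}
        assert by_term["GO:0000001"].p_bonf < 0.05
        assert by_term["GO:0000001"].direction == "enriched"
        assert all(r.p_bonf > 0.05 for t, r in by_term.items()
                   if t != "GO:0000001")

    def test_level_filter_uses_depth_column(self):
        df, go = self._planted()
        depths = {"GO:0000001": 4, "GO:0000002": 4, "GO:0000003": 3}
        records = run_enrichment(df, go, term_depths=depths, level=4)
        assert {r.term for r in records} == {"GO:0000001", "GO:0000002"}
        assert all(r.n_tests == 2 for r in records)

    def test_no_terms_at_level_warns_empty(self):
        df, go = self._planted()
        with pytest.warns(UserWarning):
            assert run_enrichment(df, go, term_depths={}, level=4) == []

    def test_strata_are_independent_families(self):
        df, go = self._planted()
        rec_a = run_enrichment(df, go, stratum="paralog")
        rec_b = run_enrichment(df.iloc[:40], go, stratum="non_paralog")
        assert all(r.stratum == "paralog" for r in rec_a)
        assert all(r.stratum == "non_paralog" for r in rec_b)

    def test_bonferroni_definition(self):
        df, go = self._planted()
        for r in run_enrichment(df, go):
            assert r.p_bonf == pytest.approx(min(1.0, r.p_raw * r.n_tests))
            assert r.a + r.b + r.c + r.d_cell == len(genes_of(df))


def test_obo_min_depth_utility(tmp_path):
    from ctcf_divergence.enrichment import term_depths_from_obo

    obo = "\n\n".join([
        "format-version: 1.2",
        "[Term]\nid: GO:0000001\nname: root",
        "[Term]\nid: GO:0000002\nname: child\nis_a: GO:0000001",
        "[Term]\nid: GO:0000003\nname: grandchild\nis_a: GO:0000002",
        # two parents: the shorter path to the root defines the depth
        "[Term]\nid: GO:0000004\nname: shortcut\nis_a: GO:0000003\n"
        "is_a: GO:0000001",
    ]) + "\n"
    path = tmp_path / "mini.obo"
    path.write_text(obo)
    depths = term_depths_from_obo(str(path))
    assert depths == {"GO:0000001": 0, "GO:0000002": 1,
                      "GO:0000003": 2, "GO:0000004": 1}


class TestSubsetSelection:
    def _records(self):
        df, go = TestRunEnrichment()._planted()
        rec_par = run_enrichment(df, go, stratum="paralog")
        rec_non = run_enrichment(df.iloc[60:], go, stratum="non_paralog")
        rec_par, rec_non = mark_specific(rec_par, rec_non)
        return df, go, rec_par

    def test_pairs_with_enriched_member_selected(self):
        df, go, rec_par = self._records()
        subset = select_subset_pairs(rec_par, df, go, mode="all")
        selected_terms = {r.term for r in rec_par if r.p_bonf < 0.05
                          and r.direction == "enriched"}
        assert len(subset) > 0
        for row in subset.itertuples():
            carried = go.get(row.left_id, set()) | go.get(row.right_id, set())
            assert carried & selected_terms

    def test_no_enriched_terms_empty_subset(self):
        df, go, rec_par = self._records()
        null_records = [r for r in rec_par if r.p_bonf >= 0.05]
        assert len(select_subset_pairs(null_records, df, go)) == 0

    def test_specific_mode_is_subset_of_all_mode(self):
        df, go, rec_par = self._records()
        spec = select_subset_pairs(rec_par, df, go, mode="specific")
        everything = select_subset_pairs(rec_par, df, go, mode="all")
        assert set(spec.pair_id) <= set(everything.pair_id)
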