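import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctcf_divergence.features import (cpg_oe, ctcf_counts, delta_cpg,
                                      intergenic_distance, inter_tss_window,
                                      upstream_window)
from ctcf_divergence.genome_io import make_gene
from ctcf_divergence.interval_ops import PeakSetCollection
from ctcf_divergence.pairing import build_adjacent_pairs
from ctcf_divergence.genome_io import ParalogTable

from .oracles import oracle_count

EMPTY = ParalogTable([])


def _pair(left, right):
    (pair,) = build_adjacent_pairs([left, right], EMPTY)
    return pair


class TestCpGOE:
    def test_cgcgcg(self):
        prof = cpg_oe("CGCGCG")
        assert prof.p_cpg == pytest.approx(3 / 5, abs=1e-12)
        assert prof.p_c == pytest.approx(0.5)
        assert prof.p_g == pytest.approx(0.5)
        assert prof.cpg_oe == pytest.approx(2.4, abs=1e-12)

    def test_cg_dinucleotide(self):
        prof = cpg_oe("CG")
        assert prof.p_cpg == 1.0
        assert prof.cpg_oe == pytest.approx(4.0, abs=1e-12)

    def test_no_c_or_g_not_estimable(self):
        assert not cpg_oe("AAAA").estimable
        assert not cpg_oe("A").estimable
        assert not cpg_oe("").estimable

    def test_case_insensitive(self):
        assert cpg_oe("cgcgcg").cpg_oe == cpg_oe("CGCGCG").cpg_oe

    def test_ambiguity_characters_skipped(self):
        # N excluded from L; the C-N-G junction is not a CpG
        with_n = cpg_oe("CGNCG")
        assert with_n.p_c == pytest.approx(2 / 4)
        assert with_n.p_cpg == pytest.approx(2 / 3)

    def test_self_concatenation_changes_only_junction(self):
        # duplicating a sequence doubles every count except the junction
        # dinucleotide, which adds one CpG iff the sequence wraps C->G
        for seq in ("ACGTT", "TTGCA", "GACGC"):
            single = cpg_oe(seq)
            double = cpg_oe(seq + seq)
            L = len(seq)
            n_single = round(single.p_cpg * (L - 1))
            junction = 1 if seq[-1] == "C" and seq[0] == "G" else 0
            assert round(double.p_cpg * (2 * L - 1)) == 2 * n_single + junction
            assert double.p_c == pytest.approx(single.p_c)

    @given(st.text(alphabet="ACGTN", min_size=2, max_size=80))
    def test_estimable_iff_c_and_g_present(self, seq):
        prof = cpg_oe(seq)
        unambiguous = seq.replace("N", "")
        has_both = "C" in unambiguous and "G" in unambiguous
        assert prof.estimable == (has_both and len(unambiguous) >= 2)
        if prof.estimable:
            assert prof.cpg_oe == pytest.approx(
                prof.p_cpg / (prof.p_c * prof.p_g))


class TestUpstreamWindow:
    def test_plus_strand(self):
        gene = make_gene("g", "chr1", "+", 1000, 2000)
        # 1-based bases 500..999 -> 0-based [499, 999)
        assert upstream_window(gene) == ("chr1", 499, 999)

    def test_minus_strand(self):
        gene = make_gene("g", "chr1", "-", 1, 1000)
        # 1-based bases 1001..1500 -> 0-based [1000, 1500)
        assert upstream_window(gene) == ("chr1", 1000, 1500)

    def test_clipped_at_origin(self):
        gene = make_gene("g", "chr1", "+", 200, 900)
        chrom, lo, hi = upstream_window(gene)
        assert (lo, hi) == (0, 199)  # bases 1..199 survive clipping


class TestDistanceAndDelta:
    def test_tss_to_tss(self):
        pair = _pair(make_gene("a", "chr1", "+", 100, 150),
                     make_gene("b", "chr1", "+", 500, 600))
        assert intergenic_distance(pair) == 400

    def test_equal_tss_degenerate(self):
        # left minus-strand gene ends where right plus-strand gene starts
        pair = _pair(make_gene("a", "chr1", "-", 100, 500),
                     make_gene("b", "chr1", "+", 500, 900))
        assert intergenic_distance(pair) == 0

    def test_strand_aware_tss(self):
        pair = _pair(make_gene("a", "chr1", "-", 400, 900),
                     make_gene("b", "chr1", "+", 1200, 1500))
        assert intergenic_distance(pair) == 300

    def test_delta_cpg_symmetric_and_worked(self):
        pair = _pair(make_gene("a", "chr1", "+", 100, 150),
                     make_gene("b", "chr1", "+", 500, 600))
        cpg = {"a": cpg_oe("CGCGCG"), "b": cpg_oe("CG")}
        assert delta_cpg(pair, cpg) == pytest.approx(1.6, abs=1e-12)
        swapped = {"a": cpg["b"], "b": cpg["a"]}
        assert delta_cpg(pair, swapped) == pytest.approx(1.6, abs=1e-12)

    def test_inestimable_cpg_raises(self):
        pair = _pair(make_gene("a", "chr1", "+", 100, 150),
                     make_gene("b", "chr1", "+", 500, 600))
        with pytest.raises(ValueError):
            delta_cpg(pair, {"a": cpg_oe("AAAA"), "b": cpg_oe("CG")})


class TestCtcfCounts:
    def _pair_and_window(self):
        pair = _pair(make_gene("a", "chr1", "+", 100, 150),
                     make_gene("b", "chr1", "+", 1100, 1200))
        return pair, inter_tss_window(pair)

    def test_core_site_counted_in_both_dialects(self):
        pair, _ = self._pair_and_window()
        core = [(400, 500)]
        peaks = PeakSetCollection({
            "c1": {"chr1": core + [(600, 650)]},
            "c2": {"chr1": core + [(700, 750)]},
        })
        n_over, n_joint, density = ctcf_counts(pair, peaks)
        assert n_over == 1
        assert n_joint == 3
        assert density == pytest.approx(1 / 1000)

    def test_no_peaks(self):
        pair, _ = self._pair_and_window()
        peaks = PeakSetCollection({"c1": {"chr2": [(0, 10)]},
                                   "c2": {"chr2": [(0, 10)]}})
        assert ctcf_counts(pair, peaks) == (0, 0, 0.0)

    def test_counts_match_per_base_oracle(self):
        rng = np.random.default_rng(9)
        pair, (chrom, lo, hi) = self._pair_and_window()
        for _ in range(25):
            sets = {}
            for c in range(3):
                ivs = sorted(
                    (int(s), int(s) + int(w))
                    for s, w in zip(rng.integers(0, 2000, 6),
                                    rng.integers(1, 120, 6)))
                sets[f"c{c}"] = {"chr1": ivs}
            peaks = PeakSetCollection(sets)
            n_over, n_joint, _ = ctcf_counts(pair, peaks)
            assert n_over == oracle_count(peaks.overlapping.get("chr1", []),
                                          lo, hi)
            assert n_joint == oracle_count(peaks.joint.get("chr1", []), lo, hi)

    def test_window_covers_d_bases(self):
        pair, (chrom, lo, hi) = self._pair_and_window()
        assert hi - lo == intergenic_distance(pair)
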