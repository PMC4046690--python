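import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctcf_divergence.assoc_stats import (partial_spearman,
                                         permutation_envelope, run_table,
                                         spearman)

from .oracles import oracle_partial_spearman, oracle_spearman


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        x = [1, 2, 2, 4]
        y = [1, 3, 2, 4]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.integers(0, 6, 15).astype(float)  # heavy ties
            y = rng.normal(size=15)
            rho, p = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestPartialSpearman:
    def test_zero_controls_equals_plain_spearman(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x, y = rng.normal(size=(2, 12))
            assert partial_spearman(x, y) == spearman(x, y)

    def test_identical_variables_give_unity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        rho_p, p = partial_spearman(x, x, [z])
        assert rho_p == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_independent_controls_leave_rho_unchanged(self):
        # planted: controls carry no information about x or y
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        controls = [rng.normal(size=n), rng.normal(size=n)]
        rho, _ = spearman(x, y)
        rho_p, _ = partial_spearman(x, y, controls)
        assert rho_p == pytest.approx(rho, abs=0.03)

    def test_matches_rank_residual_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(150):
            n = int(rng.integers(6, 13))
            k = int(rng.integers(0, 3))
            data = rng.integers(0, 8, size=(2 + k, n)).astype(float)
            x, y, *controls = data
            if any(np.ptp(v) == 0 for v in data):
                continue
            rho_p, _ = partial_spearman(x, y, controls)
            assert rho_p == pytest.approx(
                oracle_partial_spearman(x, y, controls), abs=1e-10)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(10)
        for _ in range(5):
            df = pd.DataFrame(rng.normal(size=(30, 4)),
                              columns=["x", "y", "c1", "c2"])
            rho_p, p = partial_spearman(df.x, df.y, [df.c1, df.c2])
            ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                                  method="spearman")
            assert rho_p == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
            assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_symmetric_and_rank_invariant(self):
        rng = np.random.default_rng(11)
        x, y, c = rng.normal(size=(3, 25))
        rho_xy, _ = partial_spearman(x, y, [c])
        rho_yx, _ = partial_spearman(y, x, [c])
        assert rho_xy == pytest.approx(rho_yx, abs=1e-12)
        # monotone transforms leave ranks, hence rho_p, untouched
        rho_t, _ = partial_spearman(np.exp(x), y ** 3, [c])
        assert rho_t == pytest.approx(rho_xy, abs=1e-12)

    def test_collinear_controls_rejected(self):
        rng = np.random.default_rng(12)
        x, y, c = rng.normal(size=(3, 15))
        with pytest.raises(ValueError, match="collinear|singular"):
            partial_spearman(x, y, [c, c], control_names=["c1", "c1copy"])

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError, match="k\\+3"):
            partial_spearman([1, 2, 3, 4], [4, 3, 2, 1],
                             [[1, 2, 1, 2], [2, 1, 2, 1]])


class TestPermutationEnvelope:
    def test_null_statistic_falls_inside_envelope(self):
        rng = np.random.default_rng(13)
        n = 300
        c1, c2 = rng.normal(size=(2, n))
        x = c1 + rng.normal(size=n)
        y = c2 + rng.normal(size=n)  # x,y independent given nothing planted
        env = permutation_envelope(x, y, [c1, c2], n_perm=200,
                                   rng=np.random.default_rng(14))
        rho_p, _ = partial_spearman(x, y, [c1, c2])
        assert 0 < env < 0.2
        assert abs(rho_p) < 2.5 * env


class TestRunTable:
    def _features(self, n=60, seed=15):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "relation": ["paralog"] * n,
            "d": rng.integers(100, 10000, n).astype(float),
            "n_ctcf_overlap": rng.poisson(4.0, n).astype(float),
            "delta_cpg": rng.random(n),
            "expd_1r": rng.random(n) * 2,
            "expd_euc": rng.random(n) * 10,
        })
        return df

    def test_table_shape_three_x_by_two_y(self):
        table = run_table(self._features(), ["expd_1r", "expd_euc"],
                          ["d", "n_ctcf_overlap", "delta_cpg"])
        assert len(table) == 6
        assert set(table.controls.str.count(",")) == {1}

    def test_listwise_deletion_per_analysis(self):
        df = self._features()
        df.loc[:9, "expd_1r"] = np.nan
        table = run_table(df, ["expd_1r", "expd_euc"],
                          ["d", "n_ctcf_overlap", "delta_cpg"])
        assert set(table.loc[table.y == "expd_1r", "n"]) == {50}
        assert set(table.loc[table.y == "expd_euc", "n"]) == {60}

    def test_small_stratum_flagged(self):
        df = self._features(n=8)
        df["orientation"] = ["head_to_head"] * 4 + ["tail_to_tail"] * 4
        table = run_table(df, ["expd_1r"], ["d", "n_ctcf_overlap", "delta_cpg"],
                          stratify_by="orientation", min_n=10)
        assert (table.flag == "insufficient_n").all()
        assert table.rho.isna().all()
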