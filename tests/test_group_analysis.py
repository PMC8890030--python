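import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from richconn import group_analysis as ga


class TestAnova:
    # 3 groups x 3 observations x 2 columns; F frozen from hand
    # sums-of-squares (SSB/2)/(SSW/6): column 1 -> 21, column 2 -> 1/3
    G1 = np.array([[1., 5.], [2., 6.], [3., 7.]])
    G2 = np.array([[2., 5.], [3., 7.], [4., 9.]])
    G3 = np.array([[6., 4.], [7., 6.], [8., 8.]])

    def test_matches_hand_sums_of_squares(self):
        f, p = ga.one_way_anova([self.G1, self.G2, self.G3])
        assert f[0] == pytest.approx(21.0, abs=1e-10)
        assert f[1] == pytest.approx(1.0 / 3.0, abs=1e-10)
        from scipy import stats
        assert p[0] == pytest.approx(stats.f.sf(21.0, 2, 6), abs=1e-12)

    def test_matches_scipy_f_oneway(self, rng):
        from scipy import stats
        groups = [rng.standard_normal((n, 7)) for n in (5, 8, 6)]
        f, p = ga.one_way_anova(groups)
        ref = stats.f_oneway(*groups, axis=0)
        assert np.allclose(f, ref.statistic, atol=1e-10)
        assert np.allclose(p, ref.pvalue, atol=1e-10)

    def test_zero_within_variance_is_nan(self):
        groups = [np.ones((3, 1)), np.ones((3, 1)) * 2, np.ones((3, 1)) * 3]
        f, p = ga.one_way_anova(groups)
        assert np.isnan(f[0]) and np.isnan(p[0])


class TestBhFdr:
    def test_stepup_by_hand(self):
        """p = [.01,.02,.04,.05] at q=.05: the largest k with
        p(k) <= k q / m is k=4, so all four are rejected."""
        reject, adj = ga.bh_fdr([0.01, 0.02, 0.04, 0.05], q=0.05)
        assert reject.all()

    def test_degenerate_extremes(self):
        assert not ga.bh_fdr([1.0] * 5, q=0.05)[0].any()
        assert ga.bh_fdr([0.0] * 5, q=0.05)[0].all()
        flags, adj = ga.bh_fdr([], q=0.05)
        assert len(flags) == 0 and len(adj) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_flags_monotone_in_p(self, pvals):
        reject, adj = ga.bh_fdr(pvals, q=0.05)
        order = np.argsort(pvals)
        flags = reject[order]
        # once a larger p is rejected, every smaller p must be too
        assert np.all(np.diff(flags.astype(int)) <= 0)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)


class TestEdgewise:
    def test_identical_groups_nothing_significant(self, rng):
        base = rng.standard_normal((6, 30))
        z = {"HC": base.copy(), "hPSCI": base.copy(), "iPSCI": base.copy()}
        out = ga.edgewise_group_stats(z)
        assert np.allclose(out["F"].fillna(0), 0.0, atol=1e-20)
        assert not out["sig_hPSCI"].any() and not out["sig_iPSCI"].any()

    def test_planted_shift_detected_with_direction(self, rng):
        n_edges = 40
        hc = rng.standard_normal((15, n_edges)) * 0.1 + 0.5
        shifted = hc[:, :10] - 0.4  # first 10 edges attenuated
        pat = np.hstack([rng.standard_normal((15, 10)) * 0.1 + 0.1,
                         rng.standard_normal((15, 30)) * 0.1 + 0.5])
        out = ga.edgewise_group_stats(
            {"HC": hc, "hPSCI": pat, "iPSCI": pat + rng.normal(0, 0.01, pat.shape)})
        sig_dec = out["sig_hPSCI"] & out["decreased_hPSCI"]
        assert sig_dec[:10].mean() >= 0.8     # planted edges recovered
        assert sig_dec[10:].mean() <= 0.1     # unshifted edges mostly clean

    def test_q_at_least_p(self, rng):
        z = {g: rng.standard_normal((8, 25)) for g in ("HC", "hPSCI", "iPSCI")}
        out = ga.edgewise_group_stats(z, gate=False)
        ok = np.isfinite(out["q_hPSCI"])
        assert np.all(out.loc[ok, "q_hPSCI"] >= out.loc[ok, "p_hPSCI"] - 1e-12)


class TestCurvewise:
    def test_identical_groups_no_window(self, rng):
        base = rng.standard_normal((8, 10)) + 1.0
        tab = ga.curvewise_phinorm_stats(
            {"HC": base, "hPSCI": base, "iPSCI": base})
        assert ga.significant_window(tab, "hPSCI") is None

    def test_low_k_shift_yields_low_k_window(self, rng):
        hc = rng.normal(1.0, 0.03, (12, 12))
        pat = hc + np.where(np.arange(12) < 6, 0.3, 0.0)  # k=1..6 raised
        tab = ga.curvewise_phinorm_stats({"HC": hc, "hPSCI": pat + rng.normal(0, 0.03, hc.shape),
                                          "iPSCI": pat + rng.normal(0, 0.03, hc.shape)})
        for g in ("hPSCI", "iPSCI"):
            win = ga.significant_window(tab, g)
            assert win is not None
            lo, hi = win
            assert lo <= 2 and 5 <= hi <= 7
            high_k = tab[tab["k"] > 8]
            assert not high_k[f"sig_{g}"].any()

    def test_single_k_level(self, rng):
        tab = ga.curvewise_phinorm_stats(
            {"HC": rng.random((5, 1)), "hPSCI": rng.random((5, 1)),
             "iPSCI": rng.random((5, 1))})
        assert len(tab) == 1

    def test_underpopulated_k_skipped(self, rng):
        hc = rng.random((5, 2))
        pat = rng.random((5, 2))
        pat[1:, 1] = np.nan  # only one defined subject at k=2
        tab = ga.curvewise_phinorm_stats({"HC": hc, "hPSCI": pat,
                                          "iPSCI": rng.random((5, 2))})
        assert bool(tab.loc[tab["k"] == 2, "skipped"].iloc[0])


class TestAberrantNodes:
    def _stats(self, sig, dec, n_edges):
        return pd.DataFrame({"sig_hPSCI": sig, "decreased_hPSCI": dec,
                             "sig_iPSCI": [False] * n_edges,
                             "decreased_iPSCI": [False] * n_edges})

    def test_no_significant_edges_all_zero(self):
        iu, ju = np.triu_indices(5, 1)
        counts, top = ga.aberrant_node_frequency(
            self._stats([False] * len(iu), [False] * len(iu), len(iu)),
            iu, ju, 5, ["hPSCI", "iPSCI"])
        assert (counts["count_hPSCI"] == 0).all()

    def test_hub_node_ranks_first(self):
        iu = np.array([0, 1, 2, 3])
        ju = np.array([7, 7, 7, 4])
        sig = [True, True, True, False]
        counts, top = ga.aberrant_node_frequency(
            self._stats(sig, [True] * 4, 4), iu, ju, 8, ["hPSCI", "iPSCI"])
        assert counts.loc[7, "count_hPSCI"] == 3
        assert counts.loc[7, "rank_hPSCI"] == 1
        assert top["hPSCI"][0] == 7


class TestBehaviorCorrelation:
    def test_exact_linear_relation(self):
        v = pd.DataFrame({"e": [1.0, 2, 3, 4, 5]})
        s = pd.DataFrame({"moca": [2.0, 4, 6, 8, 10]})
        out = ga.behavior_correlation(v, s)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_five_point_product_moment_oracle(self):
        """r frozen from raw-sum product-moment arithmetic."""
        v = pd.DataFrame({"e": [1.0, 2, 3, 4, 6]})
        s = pd.DataFrame({"moca": [2.0, 1, 4, 3, 7]})
        out = ga.behavior_correlation(v, s)
        assert out["r"].iloc[0] == pytest.approx(0.880695566745432, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(0.048572452840239, abs=1e-10)

    def test_constant_score_reported_missing(self):
        v = pd.DataFrame({"e": [1.0, 2, 3]})
        s = pd.DataFrame({"moca": [5.0, 5, 5]})
        out = ga.behavior_correlation(v, s)
        assert np.isnan(out["r"].iloc[0])
        assert out["note"].iloc[0] == "constant input"

    def test_null_rejection_rate_near_alpha(self, rng):
        """Monte-Carlo type-I check on independent value/score pairs."""
        hits = 0
        n_tables = 1000
        for _ in range(n_tables):
            v = pd.DataFrame({"e": rng.standard_normal(12)})
            s = pd.DataFrame({"m": rng.standard_normal(12)})
            hits += int(ga.behavior_correlation(v, s)["p"].iloc[0] < 0.05)
        assert abs(hits / n_tables - 0.05) < 0.025


class TestIcc:
    RATINGS = np.array([[9., 10], [8, 7], [6, 7], [4, 5], [7, 8], [5, 4]])

    def test_toy_table_mean_squares_oracle(self):
        """ICC(2,1) frozen at 0.875 from the variance-components oracle
        (independently cross-checked against pingouin's ICC(A,1))."""
        res = ga.icc_absolute_agreement(self.RATINGS)
        assert res.icc == pytest.approx(0.875, abs=1e-10)
        assert res.reliable

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        n, k = self.RATINGS.shape
        df = pd.DataFrame({"item": np.repeat(np.arange(n), k),
                           "rater": np.tile(np.arange(k), n),
                           "score": self.RATINGS.ravel()})
        tab = pg.intraclass_corr(df, targets="item", raters="rater",
                                 ratings="score")
        ref = float(tab.loc[tab["Type"].isin(["ICC2", "ICC(A,1)"]),
                            "ICC"].iloc[0])
        res = ga.icc_absolute_agreement(self.RATINGS)
        assert res.icc == pytest.approx(ref, abs=1e-10)

    def test_identical_raters_icc_one(self):
        x = np.array([[1.0, 1], [4, 4], [2, 2], [9, 9]])
        res = ga.icc_absolute_agreement(x)
        assert res.icc == pytest.approx(1.0)
        assert res.reliable

    def test_offset_penalized_below_one(self):
        x = self.RATINGS.copy()
        x[:, 1] = x[:, 0] + 5.0
        res = ga.icc_absolute_agreement(x)
        assert res.icc == pytest.approx(0.21875, abs=1e-10)
        assert res.icc < 1.0 and not res.reliable

    def test_zero_variance_undefined(self):
        res = ga.icc_absolute_agreement(np.full((4, 2), 3.0))
        assert np.isnan(res.icc) and not res.reliable
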