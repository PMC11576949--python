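"""Statistical core: Wilcoxon conventions, channel selection, paired
centering, correlation PCA, scree rule, PC tests, IQR outliers, and the
orchestrated model/results objects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lithic_eeg import (
    BetaPowerTable,
    OutlierRule,
    PairedComparison,
    PairedTestResult,
    compare_channels,
    iqr_outliers,
    paired_center,
    pca_correlation,
    scree_components,
    select_channels,
    wilcoxon_signed_rank,
)
from lithic_eeg import test_pc_scores as run_pc_score_tests
from lithic_eeg.inference import p_from_z
from lithic_eeg.montage import CHANNELS_32
from lithic_eeg.simulate import simulate_beta_table


def _table(values: dict) -> BetaPowerTable:
    """values: condition -> subjects x channels DataFrame."""
    rows = []
    for cond, frame in values.items():
        for s in frame.index:
            for ch in frame.columns:
                rows.append({"subject": s, "condition": cond, "channel": ch,
                             "beta_uv": float(frame.loc[s, ch])})
    return BetaPowerTable(pd.DataFrame(rows))


class TestWilcoxon:
    def test_all_positive_unit_differences_n5(self):
        r = wilcoxon_signed_rank(np.arange(5) + 2.0, np.arange(5) + 1.0)
        assert r.W == 15.0
        assert r.small_n
        assert abs(r.p_exact - 0.0625) < 1e-12
        # normal approximation with tie correction
        assert r.p == pytest.approx(p_from_z(r.Z))

    def test_identical_samples_refused(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match="too few"):
            wilcoxon_signed_rank(x, x)

    def test_sign_convention(self):
        """Z < 0 when the first sample tends to be smaller."""
        rng = np.random.default_rng(0)
        b = rng.uniform(1, 2, 20)
        r = wilcoxon_signed_rank(b - 0.5, b)
        assert r.Z < 0
        r2 = wilcoxon_signed_rank(b + 0.5, b)
        assert r2.Z > 0

    def test_matches_scipy_no_correction(self, rng):
        """Dual route: same W and p as scipy's zero-dropping,
        approximation-mode, uncorrected Wilcoxon."""
        for _ in range(25):
            n = int(rng.integers(8, 40))
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            ours = wilcoxon_signed_rank(a, b)
            sp = stats.wilcoxon(a, b, zero_method="wilcox", correction=False,
                                method="approx")
            assert min(ours.W, ours.n * (ours.n + 1) / 2 - ours.W) == \
                pytest.approx(sp.statistic)
            assert ours.p == pytest.approx(sp.pvalue, rel=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_exact_p_valid_probability(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        r = wilcoxon_signed_rank(a, b)
        if r.p_exact is not None:
            assert 0 < r.p_exact <= 1


class TestCompareChannels:
    def test_26_of_32_channels_tested(self):
        df = simulate_beta_table(10, conditions=["cut.hold", "cut.aim"], seed=0)
        res = compare_channels(BetaPowerTable(df), "cut.hold", "cut.aim")
        assert len(res) == 26
        tested = {r.channel for r in res}
        assert tested.isdisjoint({"Fp1", "Fp2", "TP9", "TP10", "FT9", "FT10"})

    def test_uniform_shift_gives_uniform_negative_z(self):
        rng = np.random.default_rng(1)
        # quarter-unit grid keeps the +0.5 shift exactly representable
        base = pd.DataFrame(rng.integers(4, 13, (12, 32)) / 4.0,
                            index=[f"S{i}" for i in range(12)],
                            columns=list(CHANNELS_32))
        table = _table({"a.hold": base, "a.aim": base + 0.5})
        res = compare_channels(table, "a.hold", "a.aim")
        assert all(r.Z < 0 for r in res)
        assert len({round(r.p, 12) for r in res}) == 1

    def test_too_few_shared_subjects(self):
        df = simulate_beta_table(4, conditions=["cut.hold", "cut.aim"], seed=0)
        with pytest.raises(ValueError, match="shared subjects"):
            compare_channels(BetaPowerTable(df), "cut.hold", "cut.aim")


class TestSelection:
    @staticmethod
    def _result(ch, z, p):
        return PairedTestResult(ch, 23, 100.0, z, p)

    def test_reported_holding_comparison_ordering(self):
        """The five significant channels of the hold-vs-hold worked
        example, ordered by |Z| with the O2/P8 tie broken by montage
        order."""
        printed = {"FC1": -2.14, "CP1": -2.24, "O2": -2.27, "P8": -2.27,
                   "Cz": -2.11}
        results = []
        for ch in CHANNELS_32:
            if ch in ("Fp1", "Fp2", "TP9", "TP10", "FT9", "FT10"):
                continue
            if ch in printed:
                z = printed[ch]
                results.append(self._result(ch, z, p_from_z(z)))
            else:
                results.append(self._result(ch, -1.0, p_from_z(1.0)))
        sel = select_channels(results, "hold vs hold")
        assert sel.channels == ("O2", "P8", "CP1", "FC1", "Cz")
        assert sel.rule_used == "significant-ranked"

    def test_fallback_with_two_significant(self):
        results = [self._result(f"C{i}", 0.1 * i, 0.5) for i in range(1, 9)]
        results += [self._result("Cz", -2.8, 0.005),
                    self._result("Pz", -2.5, 0.01)]
        sel = select_channels(results)
        assert sel.rule_used == "top-absZ-fallback"
        assert {"Cz", "Pz"} <= set(sel.channels)

    def test_full_tie_uses_montage_order(self):
        chans = ["Cz", "O2", "F3", "Pz", "C3", "Fz", "P8"]
        results = [self._result(c, 1.5, 0.13) for c in chans]
        sel = select_channels(results)
        expect = sorted(chans, key=CHANNELS_32.index)[:5]
        assert list(sel.channels) == expect

    def test_input_order_invariance(self, rng):
        results = [self._result(c, float(z), 0.2)
                   for c, z in zip(CHANNELS_32[:10], rng.standard_normal(10))]
        sel1 = select_channels(list(results))
        rng.shuffle(results)
        sel2 = select_channels(list(results))
        assert sel1.channels == sel2.channels


class TestPairedCenter:
    def test_arithmetic_example(self):
        a = pd.DataFrame({"Cz": [4.0]}, index=["S1"])
        b = pd.DataFrame({"Cz": [2.0]}, index=["S1"])
        # need >= 5 subjects for the table wrapper? centering itself is fine
        table = _table({"x.hold": a, "x.aim": b})
        c = paired_center(table, "x.hold", "x.aim")
        assert c.loc[("S1", "x.hold"), "Cz"] == 1.0
        assert c.loc[("S1", "x.aim"), "Cz"] == -1.0

    def test_equal_values_center_to_zero(self):
        a = pd.DataFrame({"Cz": [3.0, 5.0]}, index=["S1", "S2"])
        table = _table({"x.hold": a, "x.aim": a})
        c = paired_center(table, "x.hold", "x.aim")
        assert np.allclose(c.to_numpy(), 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        subs = [f"S{i}" for i in range(n)]
        cols = ["Cz", "Pz", "F3"]
        a = pd.DataFrame(rng.uniform(0.1, 5, (n, 3)), index=subs, columns=cols)
        b = pd.DataFrame(rng.uniform(0.1, 5, (n, 3)), index=subs, columns=cols)
        c = paired_center(_table({"t.hold": a, "t.aim": b}), "t.hold", "t.aim")
        xa = c.xs("t.hold", level="condition")
        xb = c.xs("t.aim", level="condition")
        assert np.allclose(xa.to_numpy() + xb.to_numpy(), 0.0)


class TestPCA:
    def _centered(self, X, cols=None):
        n = X.shape[0] // 2
        cols = cols or [f"ch{i}" for i in range(X.shape[1])]
        idx = pd.MultiIndex.from_tuples(
            [(f"S{i}", "A") for i in range(n)] +
            [(f"S{i}", "B") for i in range(n)],
            names=["subject", "condition"])
        return pd.DataFrame(X, index=idx, columns=cols)

    def test_perfectly_correlated_pair(self, rng):
        n = 40
        base = rng.standard_normal(n)
        X = np.column_stack([base, 2 * base] +
                            [rng.standard_normal(n) for _ in range(3)])
        X = np.vstack([X, -X])
        rep = pca_correlation(self._centered(X))
        l1 = rep.loadings["PC1"].to_numpy()
        assert abs(abs(l1[0]) - abs(l1[1])) < 1e-8

    def test_variance_sums_to_100(self, rng):
        X = rng.standard_normal((30, 5))
        X = np.vstack([X, -X])
        rep = pca_correlation(self._centered(X))
        assert rep.var_explained.sum() == pytest.approx(100.0, abs=1e-6)

    def test_independent_columns_near_uniform_at_large_n(self, rng):
        X = rng.standard_normal((4000, 5))
        X = np.vstack([X, -X])
        rep = pca_correlation(self._centered(X))
        assert np.all(np.abs(rep.var_explained - 20.0) < 4.0)

    def test_matches_sklearn(self, rng):
        """Dual route: variance ratios and |loadings| against sklearn PCA
        on standardized data."""
        from sklearn.decomposition import PCA

        X = rng.standard_normal((25, 5))
        X = np.vstack([X, -X])
        rep = pca_correlation(self._centered(X))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        sk = PCA(n_components=5).fit(Z)
        assert np.allclose(rep.var_explained / 100.0,
                           sk.explained_variance_ratio_, atol=1e-8)
        assert np.allclose(np.abs(rep.loadings.to_numpy().T),
                           np.abs(sk.components_), atol=1e-6)

    def test_zero_variance_column_reported(self):
        X = np.ones((12, 5))
        X[:, 1:] = np.random.default_rng(0).standard_normal((12, 4))
        rep_in = self._centered(X, cols=["flat", "a", "b", "c", "d"])
        with pytest.raises(ValueError, match="flat"):
            pca_correlation(rep_in)

    def test_mirrored_score_pairs(self, rng):
        """Paired centering makes score(s, A) = -score(s, B) on every axis."""
        X = rng.standard_normal((20, 5))
        X = np.vstack([X, -X])
        rep = pca_correlation(self._centered(X))
        sa = rep.scores.xs("A", level="condition").to_numpy()
        sb = rep.scores.xs("B", level="condition").to_numpy()
        assert np.allclose(sa, -sb, atol=1e-10)


class TestScree:
    @pytest.mark.parametrize("var,expected", [
        ([61.6, 18.2, 10, 6, 4.2], 2),
        ([20, 20, 20, 20, 20], 2),
        ([90, 5, 3, 1, 1], 2),
        ([40, 35, 10, 10, 5], 2),
        ([30, 28, 26, 10, 6], 3),
    ])
    def test_rule(self, var, expected):
        assert scree_components(var) == expected

    def test_needs_two_components(self):
        with pytest.raises(ValueError):
            scree_components([100.0])


class TestPCScores:
    def test_structural_identity(self, rng):
        """Mirrored scores mean the test runs on doubled condition-A
        scores; Z sign follows the A-score mean sign."""
        X = rng.standard_normal((20, 5)) + 0.8
        X = np.vstack([X, -X])
        rep = TestPCA()._centered(X)
        report = pca_correlation(rep)
        report = run_pc_score_tests(report, "A", "B")
        sa = report.scores.xs("A", level="condition")["PC1"]
        t = report.pc_tests[0]
        assert np.sign(t.Z) == np.sign(sa.mean())


class TestIQROutliers:
    def _series(self, values):
        idx = pd.MultiIndex.from_tuples(
            [(f"S{i}", "A") for i in range(len(values))],
            names=["subject", "condition"])
        return pd.Series(values, index=idx)

    def test_symmetric_scores_no_outliers(self):
        assert iqr_outliers(self._series([-2, -1, 0, 1, 2])) == set()

    def test_hand_computed_fences(self):
        """{-1,-1,0,1,1,25}: Q1=-0.75, Q3=1, IQR=1.75 -> upper fence
        3.625, so only the 25 is flagged."""
        out = iqr_outliers(self._series([-1, -1, 0, 1, 1, 25]))
        assert out == {"S5"}

    def test_huge_k_flags_nothing(self):
        out = iqr_outliers(self._series([-1, -1, 0, 1, 1, 25]),
                           OutlierRule(k=1e9))
        assert out == set()

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="5 subjects"):
            iqr_outliers(self._series([1, 2, 3]))


class TestModelResults:
    def test_self_comparison_refused(self):
        df = simulate_beta_table(8, conditions=["cut.hold"], seed=0)
        with pytest.raises(ValueError, match="itself"):
            PairedComparison(BetaPowerTable(df), "cut.hold", "cut.hold")

    def test_injected_effect_recovered_and_summarised(self):
        from lithic_eeg import EffectMap

        eff = EffectMap({(c, "cut.hold"): 1.4 for c in ("FC1", "Cz", "CP1")})
        df = simulate_beta_table(23, eff,
                                 conditions=["nutcrack.hold", "cut.hold"],
                                 seed=11)
        res = PairedComparison.from_dataframe(df, "nutcrack.hold",
                                              "cut.hold").fit()
        assert len(set(res.selection.channels) & {"FC1", "Cz", "CP1"}) >= 2
        assert res.pca.pc_tests[0].p < 0.05
        text = res.summary()
        assert "PC1" in text and "selected channels" in text

    def test_single_outlier_rerun(self):
        eff_df = simulate_beta_table(12, conditions=["a.hold", "a.aim"],
                                     seed=3,
                                     measurement_sd=0.05)
        # force a strong effect plus one wild subject
        eff_df.loc[(eff_df.condition == "a.aim"), "beta_uv"] *= 1.5
        wild = (eff_df.subject == "S01") & (eff_df.condition == "a.aim")
        eff_df.loc[wild, "beta_uv"] *= 30.0
        res = PairedComparison.from_dataframe(eff_df, "a.hold", "a.aim").fit()
        assert res.rerun
        assert "S01" in res.outliers_removed
        assert res.first_pass is not None

    def test_channel_frame_has_supplementary_bh(self):
        df = simulate_beta_table(10, conditions=["cut.hold", "cut.aim"], seed=0)
        res = PairedComparison.from_dataframe(df, "cut.hold", "cut.aim").fit()
        frame = res.channel_frame()
        assert "p_bh_supplementary" in frame.columns
        assert (frame["p_bh_supplementary"] >= frame["p"] - 1e-12).all()
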