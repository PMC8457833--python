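"""Statistical battery: printed worked examples, oracle equivalences,
cross-checks against independent implementations, and null calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import dendrocalc as dc
from dendrocalc import StatSummaryPair


class TestOneSampleT:
    @pytest.mark.parametrize("mean,sem,n,printed_t", [
        (-14.3, 3.37, 13, -4.2),    # proximal hyperosmotic effect
        (-80.3, 3.5, 5, -22.9),     # calcium-free proximal
        (32.0, 10.7, 10, 3.0),      # hypoosmotic distal increase
        (-63.4, 8.7, 8, -7.3),      # distal eEPSC reduction
        (-33.13, 7.5, 10, -4.4),    # current-clamp distal
        (15.4, 5.42, 6, 2.8),       # muscimol tonic current
    ])
    def test_reproduces_printed_statistics(self, mean, sem, n, printed_t):
        res = dc.t_from_summary(mean, sem, n)
        assert round(res.statistic, 1) == printed_t
        assert res.df == n - 1

    def test_matches_scipy_on_raw_data(self, rng):
        x = rng.normal(1.2, 3.0, size=14)
        res = dc.one_sample_t(x, mu0=0.5)
        from scipy.stats import ttest_1samp
        ref = ttest_1samp(x, 0.5)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_symmetric_data_gives_t_zero(self):
        res = dc.one_sample_t([1.0, 2.0, 3.0, 4.0, 5.0], mu0=3.0)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            dc.one_sample_t([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            dc.one_sample_t([1.0])


class TestTwoSampleT:
    def test_welch_reproduces_printed_input_resistance_contrast(self):
        """R_input of magnocellular vs parvocellular cells: printed t=7.5."""
        res = dc.two_sample_t(StatSummaryPair(1836.87, 107.84, 62),
                              StatSummaryPair(854.81, 73.92, 22))
        assert res.correction == "welch"   # variance pre-test fires
        assert round(res.statistic, 1) == 7.5
        assert res.p < 1e-4

    def test_matches_scipy_both_modes(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.4, 3.0, 12)
        from scipy.stats import ttest_ind
        for force, equal_var in (("pooled", True), ("welch", False)):
            res = dc.two_sample_t(a, b, force=force)
            ref = ttest_ind(a, b, equal_var=equal_var)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_groups_give_zero(self, rng):
        x = rng.normal(size=10)
        res = dc.two_sample_t(x, x.copy())
        assert res.statistic == 0.0

    def test_swapping_groups_flips_sign(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 11)
        r1, r2 = dc.two_sample_t(a, b), dc.two_sample_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)


class TestPairedT:
    def test_equals_one_sample_on_differences(self, rng):
        x = rng.normal(size=10)
        y = x + rng.normal(0.5, 0.3, size=10)
        res = dc.paired_t(x, y)
        ref = dc.one_sample_t(x - y, 0.0)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-14)
        assert res.p == pytest.approx(ref.p, rel=1e-14)

    def test_zero_variance_differences_rejected(self):
        x = np.asarray([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            dc.paired_t(x, x + 2.0)

    def test_antisymmetric_differences_give_zero(self):
        x = np.asarray([0.0, 0.0, 0.0, 0.0])
        y = np.asarray([-2.0, -1.0, 1.0, 2.0])
        assert dc.paired_t(x, y).statistic == 0.0


class TestPearson:
    def test_perfect_correlations(self):
        x = np.asarray([1.0, 2.0, 3.0, 4.0])
        assert dc.pearson_r(x, 2 * x).statistic == pytest.approx(1.0)
        assert dc.pearson_r(x, -x).statistic == pytest.approx(-1.0)
        assert dc.pearson_r(x, 2 * x).p == 0.0

    def test_null_distribution_centred_on_zero(self):
        rs = []
        for s in range(300):
            r = np.random.default_rng(s)
            rs.append(dc.pearson_r(r.normal(size=12),
                                   r.normal(size=12)).statistic)
        rs = np.asarray(rs)
        assert abs(rs.mean()) < 3 * rs.std(ddof=1) / np.sqrt(len(rs))

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        from scipy.stats import pearsonr
        res = dc.pearson_r(x, y)
        ref = pearsonr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestRmAnovaOneway:
    def test_k2_equals_paired_t_squared(self, rng):
        """With two levels the within-subject F is the paired t squared."""
        for s in range(25):
            r = np.random.default_rng(s)
            X = r.normal(size=(8, 2)) + r.normal(size=(8, 1))
            res = dc.rm_anova_oneway(X)
            tres = dc.paired_t(X[:, 0], X[:, 1])
            assert res.statistic == pytest.approx(tres.statistic ** 2,
                                                  abs=1e-10)
            assert res.p == pytest.approx(tres.p, abs=1e-10)

    def test_identical_columns_give_f_zero(self, rng):
        col = rng.normal(size=9)
        X = np.tile(col[:, None], (1, 4))
        res = dc.rm_anova_oneway(X)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_compound_symmetry_keeps_epsilon_near_one(self):
        """Spherical (compound-symmetric) data: median GG epsilon over
        simulations >= 0.95.  The estimator is biased downward in small
        samples, so the consistency check uses enough subjects for the
        bias to be negligible."""
        eps = []
        for s in range(200):
            r = np.random.default_rng(s)
            X = r.normal(size=(200, 4)) + r.normal(size=(200, 1))
            eps.append(dc.gg_epsilon(X))
        assert np.median(eps) >= 0.95

    def test_matches_pingouin_with_gg_correction(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(12, 4)) @ np.diag([1.0, 2.5, 0.6, 1.5]) \
            + rng.normal(size=(12, 1))
        res = dc.rm_anova_oneway(X, gg="auto")
        n, k = X.shape
        df = pd.DataFrame({"y": X.ravel(),
                           "subj": np.repeat(np.arange(n), k),
                           "cond": np.tile(np.arange(k), n)})
        aov = pg.rm_anova(dv="y", within="cond", subject="subj", data=df,
                          correction=True, detailed=True)
        assert res.statistic == pytest.approx(aov.loc[0, "F"], rel=1e-9)
        assert res.epsilon == pytest.approx(aov.loc[0, "eps"], rel=1e-9)
        if res.correction == "greenhouse-geisser":
            assert res.p == pytest.approx(aov.loc[0, "p_GG_corr"], rel=1e-6)

    def test_missing_cells_rejected(self):
        X = np.ones((5, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            dc.rm_anova_oneway(X)


class TestMauchlyAndEpsilon:
    def test_two_levels_trivially_spherical(self, rng):
        res = dc.mauchly(rng.normal(size=(10, 2)))
        assert res.statistic == 1.0 and res.p == 1.0
        assert dc.gg_epsilon(rng.normal(size=(10, 2))) == 1.0

    def test_w_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(14, 4)) @ np.diag([1.0, 3.0, 0.5, 1.0])
        res = dc.mauchly(X)
        n, k = X.shape
        df = pd.DataFrame({"y": X.ravel(),
                           "subj": np.repeat(np.arange(n), k),
                           "cond": np.tile(np.arange(k), n)})
        sph = pg.sphericity(df, dv="y", within="cond", subject="subj")
        assert res.statistic == pytest.approx(sph.W, rel=1e-9)
        # first-order Box approximation: p agrees to leading order
        assert res.p == pytest.approx(sph.pval, rel=0.2)

    def test_rejection_rate_near_alpha_under_sphericity(self):
        rejections = 0
        sims = 400
        for s in range(sims):
            r = np.random.default_rng(s)
            X = r.normal(size=(15, 3))
            if dc.mauchly(X).p < 0.05:
                rejections += 1
        rate = rejections / sims
        assert 0.02 <= rate <= 0.09

    def test_heteroscedastic_contrasts_reduce_w(self, rng):
        X = rng.normal(size=(12, 3)) @ np.diag([1.0, 5.0, 0.2])
        assert dc.mauchly(X).statistic < 1.0

    def test_epsilon_stays_in_theoretical_range(self):
        for s in range(100):
            r = np.random.default_rng(s)
            k = int(r.integers(3, 6))
            X = r.normal(size=(k + 3, k)) @ np.diag(r.uniform(0.2, 3.0, k))
            eps = dc.gg_epsilon(X)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


class TestRmAnovaTwoway:
    def test_mixed_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        g1 = rng.normal(size=(7, 3))
        g2 = rng.normal(size=(5, 3)) + 0.6     # unbalanced groups
        out = dc.rm_anova_twoway({"k": g1, "cs": g2}, design="mixed",
                                 gg="never")
        rows = []
        for lbl, m in (("k", g1), ("cs", g2)):
            for i in range(m.shape[0]):
                for j in range(m.shape[1]):
                    rows.append(dict(y=m[i, j], subj=f"{lbl}{i}",
                                     grp=lbl, w=j))
        aov = pg.mixed_anova(dv="y", within="w", subject="subj",
                             between="grp", data=pd.DataFrame(rows))
        by_src = aov.set_index("Source")
        assert out["between"].statistic == pytest.approx(
            by_src.loc["grp", "F"], rel=1e-9)
        assert out["within"].statistic == pytest.approx(
            by_src.loc["w", "F"], rel=1e-9)
        assert out["interaction"].statistic == pytest.approx(
            by_src.loc["Interaction", "F"], rel=1e-9)

    def test_fully_within_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(8, 2, 3)) + np.arange(3)[None, None, :] * 0.5
        out = dc.rm_anova_twoway(X, design="within", gg="never")
        rows = [dict(y=X[i, a, b], subj=i, A=a, B=b)
                for i in range(8) for a in range(2) for b in range(3)]
        aov = pg.rm_anova(dv="y", within=["A", "B"], subject="subj",
                          data=pd.DataFrame(rows)).set_index("Source")
        assert out["factor_a"].statistic == pytest.approx(
            aov.loc["A", "F"], rel=1e-9)
        assert out["factor_b"].statistic == pytest.approx(
            aov.loc["B", "F"], rel=1e-9)
        assert out["interaction"].statistic == pytest.approx(
            aov.loc["A * B", "F"], rel=1e-9)

    def test_dummy_between_factor_has_zero_f(self, rng):
        """Duplicating every subject across a fake group nulls the
        between-factor effect."""
        g = rng.normal(size=(6, 3))
        out = dc.rm_anova_twoway({"a": g, "b": g.copy()}, design="mixed")
        assert out["between"].statistic == pytest.approx(0.0, abs=1e-20)
        assert out["interaction"].statistic == pytest.approx(0.0, abs=1e-20)

    def test_single_within_level_reduces_to_between_anova(self, rng):
        """With one within level the mixed design is a one-way between
        ANOVA on the subject values; for two groups F = pooled t^2."""
        a = rng.normal(size=(8, 1))
        b = rng.normal(0.9, 1.0, size=(7, 1))
        out = dc.rm_anova_twoway({"a": a, "b": b}, design="mixed")
        tres = dc.two_sample_t(a.ravel(), b.ravel(), force="pooled")
        assert out["between"].statistic == pytest.approx(
            tres.statistic ** 2, rel=1e-10)
        assert out["between"].p == pytest.approx(tres.p, rel=1e-10)

    def test_between_design_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols
        cells = {(a, b): rng.normal(a * 0.5, 1.0, size=6)
                 for a in (0, 1) for b in (0, 1, 2)}
        out = dc.rm_anova_twoway(cells, design="between")
        rows = [dict(y=v, A=str(a), B=str(b))
                for (a, b), vals in cells.items() for v in vals]
        model = ols("y ~ C(A) * C(B)", data=pd.DataFrame(rows)).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        assert out["factor_a"].statistic == pytest.approx(
            aov.loc["C(A)", "F"], rel=1e-9)
        assert out["factor_b"].statistic == pytest.approx(
            aov.loc["C(B)", "F"], rel=1e-9)
        assert out["interaction"].statistic == pytest.approx(
            aov.loc["C(A):C(B)", "F"], rel=1e-9)


class TestHolmSidak:
    def test_hand_computed_oracle(self):
        adj = dc.holm_sidak([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.029701, 0.0591, 0.0591], abs=5e-5)

    def test_single_and_saturated(self):
        assert dc.holm_sidak([0.2]) == pytest.approx([0.2])
        assert dc.holm_sidak([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0),
                     min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adjusted_never_below_raw_and_equivariant(self, ps):
        adj = dc.holm_sidak(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        perm = np.argsort(ps)[::-1]
        adj_perm = dc.holm_sidak(list(np.asarray(ps)[perm]))
        assert np.allclose(adj[perm], adj_perm)

    def test_monotone_in_sorted_order(self, rng):
        ps = rng.uniform(size=12)
        adj = dc.holm_sidak(ps)
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestNernst:
    def test_equal_concentrations_no_shift(self):
        assert dc.nernst_shift(2.4, 2.4) == 0.0

    def test_calcium_dilution_below_printed_bound(self):
        """2.4 -> 2.16 mM calcium at 28 C shifts E_Ca by ~1.37 mV < 2 mV."""
        shift = dc.nernst_shift(2.4, 2.16, z=2, temperature_C=28.0)
        assert shift == pytest.approx(1.37, abs=0.005)
        assert shift < 2.0

    def test_halving_valence_doubles_shift(self):
        assert dc.nernst_shift(2.4, 2.16, z=1) == pytest.approx(
            2 * dc.nernst_shift(2.4, 2.16, z=2), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dc.nernst_shift(0.0, 2.0)
        with pytest.raises(ValueError):
            dc.nernst_shift(2.0, 2.0, z=0)


class TestTypeIError:
    """Null calibration at alpha=0.05; binomial 95% band for the rates."""

    def band(self, sims):
        half = 1.96 * np.sqrt(0.05 * 0.95 / sims)
        return 0.05 - half, 0.05 + half

    def test_one_sample_t_null_rate(self):
        sims, n = 4000, 10
        rng = np.random.default_rng(77)
        x = rng.normal(size=(sims, n))
        t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
        from scipy.stats import t as tdist
        rate = (2 * tdist.sf(np.abs(t), n - 1) < 0.05).mean()
        lo, hi = self.band(sims)
        # vectorized replica of one_sample_t; spot-check agreement
        res = dc.one_sample_t(x[0])
        assert res.statistic == pytest.approx(t[0], rel=1e-12)
        assert lo <= rate <= hi

    def test_welch_t_null_rate(self):
        sims = 2000
        rng = np.random.default_rng(78)
        rejections = 0
        for _ in range(sims):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0, 2, 14)
            if dc.two_sample_t(a, b, force="welch").p < 0.05:
                rejections += 1
        lo, hi = self.band(sims)
        assert lo <= rejections / sims <= hi

    def test_rm_anova_null_rate(self):
        sims = 1500
        rng = np.random.default_rng(79)
        rejections = 0
        for _ in range(sims):
            X = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1))
            if dc.rm_anova_oneway(X).p < 0.05:
                rejections += 1
        lo, hi = self.band(sims)
        assert lo <= rejections / sims <= hi
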