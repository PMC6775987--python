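import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from micrortf import stats as st


class TestCurveFits:
    def test_exact_linear_recovered(self):
        x = np.linspace(1, 60, 40)
        y = 2.0 + 0.5 * x
        fr = st.fit_diversity_function(x, y)
        assert fr.selected == "linear"
        assert fr.fits["linear"]["params"][1] == pytest.approx(0.5, abs=1e-6)

    def test_constant_series_selects_linear_by_tie_rule(self):
        x = np.linspace(1, 30, 30)
        y = np.full_like(x, 5.0)
        fr = st.fit_diversity_function(x, y)
        assert fr.selected == "linear"
        assert fr.fits["linear"]["params"][1] == pytest.approx(0.0, abs=1e-9)

    def test_hyperbolic_recovery_with_noise(self):
        x = np.linspace(1, 60, 60)
        v_hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 10.0 * x / (5.0 + x) + rng.normal(0, 0.05, x.size)
            fr = st.fit_diversity_function(x, y)
            assert fr.selected == "hyperbolic"
            v, k = fr.fits["hyperbolic"]["params"]
            v_hits.append(abs(v - 10.0) / 10.0 < 0.1 and abs(k - 5.0) / 5.0 < 0.1)
        assert np.mean(v_hits) == 1.0

    def test_confidence_band_brackets_truth(self):
        x = np.linspace(1, 60, 60)
        rng = np.random.default_rng(0)
        y = 1.0 + 0.3 * x + rng.normal(0, 0.5, x.size)
        fr = st.fit_diversity_function(x, y, band=True, n_mc=2000, rng=1)
        grid = fr.band["grid"]
        truth = 1.0 + 0.3 * grid
        inside = (truth >= fr.band["low"]) & (truth <= fr.band["high"])
        assert inside.mean() > 0.9
        assert np.all(fr.band["low"] <= fr.band["high"])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            st.fit_diversity_function([1, 2, 3], [1, 2, 3])


class TestRichnessBinTests:
    def test_all_values_at_null_give_p_one(self):
        vals = np.ones(30)
        rich = np.linspace(2, 40, 30)
        out = st.richness_bin_tests(vals, rich)
        done = out[~out["skipped"]]
        assert np.allclose(done["t"].abs(), 0.0)
        assert np.allclose(done["p"], 1.0)

    def test_power_against_shifted_values(self):
        rng = np.random.default_rng(0)
        vals = 1.5 + rng.normal(0, 0.1, 30)
        rich = np.full(30, 5.0)
        out = st.richness_bin_tests(vals, rich)
        row = out[out["bin"] == "<= 12"].iloc[0]
        assert row["p"] < 1e-6

    def test_undersized_bin_skipped(self):
        out = st.richness_bin_tests([1.0, 1.1], [5, 6])
        assert bool(out[out["bin"] == "<= 12"]["skipped"].iloc[0]) is True

    def test_paired_identical_vectors_give_p_one(self):
        a = np.array([1.0, 1.2, 0.9, 1.1, 1.3])
        out = st.paired_bin_tests(a, a.copy(), np.full(5, 5.0))
        row = out[out["bin"] == "<= 12"].iloc[0]
        assert row["p_wilcoxon"] == pytest.approx(1.0)

    def test_paired_detects_consistent_difference(self):
        rng = np.random.default_rng(1)
        b = rng.normal(1.0, 0.05, 20)
        a = b + 0.2
        out = st.paired_bin_tests(a, b, np.full(20, 5.0), alternative="greater")
        row = out[out["bin"] == "<= 12"].iloc[0]
        assert row["p_wilcoxon"] < 0.01 and row["p_t"] < 1e-6


class TestScaledComparison:
    def _fit(self, x, y):
        return st.fit_diversity_function(x, y)

    def test_identical_fits_compare_equal(self):
        x = np.linspace(1, 50, 30)
        y = 3 * x / (4 + x)
        fa = self._fit(x, y)
        out = st.scaled_comparison(fa, fa, np.linspace(1, 50, 25))
        assert out["p"] == 1.0 and out["t"] == 0.0

    def test_scalar_multiple_is_scale_invariant(self):
        x = np.linspace(1, 50, 30)
        y = 3 * x / (4 + x)
        fa = self._fit(x, y)
        fb = self._fit(x, 10 * y)
        out = st.scaled_comparison(fa, fb, np.linspace(1, 50, 25))
        assert out["p"] == pytest.approx(1.0)

    def test_small_k_curve_dominates_after_scaling(self):
        # scaled Michaelis-Menten curves: smaller K saturates earlier, so it
        # lies above the large-K curve at every interior grid point
        x = np.linspace(1, 100, 80)
        fa = self._fit(x, 10 * x / (5 + x))
        fb = self._fit(x, 10 * x / (30 + x))
        grid = np.linspace(1, 100, 50)
        out = st.scaled_comparison(fa, fb, grid)
        assert out["mean_diff"] > 0
        assert out["t"] > 0
        assert out["p"] < 1e-10


class TestKendallTau:
    def test_matches_brute_force_oracle_with_ties(self):
        def brute_tau_b(a, b):
            n = len(a)
            s = n1 = n2 = 0
            for i in range(n):
                for j in range(i + 1, n):
                    da, db = np.sign(a[i] - a[j]), np.sign(b[i] - b[j])
                    s += da * db
                    n1 += da == 0
                    n2 += db == 0
            n0 = n * (n - 1) / 2
            return s / np.sqrt((n0 - n1) * (n0 - n2))

        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(4, 31))
            a = rng.integers(0, 8, n).astype(float)
            b = rng.integers(0, 8, n).astype(float)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            tau, _ = st.kendall_tau_b(a, b)
            assert tau == pytest.approx(brute_tau_b(a, b), abs=1e-12)
            checked += 1
        assert checked >= 80

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 25))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            tau, p = st.kendall_tau_b(a, b)
            ref = sps.kendalltau(a, b, method="asymptotic")
            assert tau == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestSlidingWindowScreen:
    def _random_inputs(self, rng, n=40, n_taxa=20):
        richness = pd.Series(rng.integers(5, 36, n), index=[f"C{i}" for i in range(n)])
        rel = pd.DataFrame(rng.dirichlet(np.ones(n_taxa), n), index=richness.index,
                           columns=[f"T{j}" for j in range(n_taxa)])
        f = pd.Series(rng.normal(10, 2, n), index=richness.index)
        return rel, f, richness

    def test_planted_association_detected_with_perfect_tau(self):
        rng = np.random.default_rng(3)
        richness = pd.Series(np.repeat(np.arange(10, 26), 3)[:40],
                             index=[f"C{i}" for i in range(40)])
        fv = pd.Series(rng.uniform(1, 10, 40), index=richness.index)
        rel = pd.DataFrame(rng.dirichlet(np.ones(10), 40) * 0.5,
                           index=richness.index, columns=[f"T{j}" for j in range(10)])
        rel["KEY"] = 0.5 * fv / (1 + fv.max())  # strictly increasing transform
        out = st.sliding_window_screen(rel, fv, richness)
        key = out[out["taxon_id"] == "KEY"]
        assert len(key) > 0
        assert np.allclose(key["tau"], 1.0)
        assert key["hit"].any()

    def test_null_calibration_under_permutation(self):
        rng = np.random.default_rng(7)
        rel, f, richness = self._random_inputs(rng)
        hits = []
        for _ in range(25):
            fp = pd.Series(rng.permutation(f.to_numpy()), index=f.index)
            out = st.sliding_window_screen(rel, fp, richness)
            hits.append(int(out["hit"].sum()))
        assert np.mean(hits) < 0.5

    def test_constant_function_yields_no_tests(self):
        rng = np.random.default_rng(1)
        rel, f, richness = self._random_inputs(rng)
        out = st.sliding_window_screen(rel, pd.Series(5.0, index=f.index), richness)
        assert len(out) == 0

    def test_q_values_monotone_in_p_within_stratum(self):
        rng = np.random.default_rng(2)
        rel, f, richness = self._random_inputs(rng)
        out = st.sliding_window_screen(rel, f, richness)
        assert (out["q"] <= 1.0 + 1e-12).all()
        assert (out["q"] >= out["p"] - 1e-12).all()
        for _, g in out.groupby("width"):
            g = g.sort_values("p")
            assert (g["q"].diff().dropna() >= -1e-12).all()


class TestLoreauHector:
    def test_observed_equals_expected_gives_zero_effects(self):
        mono = pd.Series({"a": 10.0, "b": 20.0})
        exp_ry = pd.Series({"a": 0.5, "b": 0.5})
        obs = mono * exp_ry
        p = st.loreau_hector_partition(obs, mono, exp_ry)
        assert p.net == pytest.approx(0.0, abs=1e-12)
        assert p.complementarity == pytest.approx(0.0, abs=1e-12)
        assert p.selection == pytest.approx(0.0, abs=1e-12)

    def test_identity_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = int(rng.integers(2, 8))
            idx = [f"t{i}" for i in range(k)]
            mono = pd.Series(rng.uniform(1, 20, k), index=idx)
            ry = rng.dirichlet(np.ones(k))
            obs = pd.Series(rng.uniform(0.1, 30, k), index=idx)
            p = st.loreau_hector_partition(obs, mono, pd.Series(ry, index=idx))
            assert p.net == pytest.approx(p.complementarity + p.selection, abs=1e-12)

    def test_equal_monocultures_link_complementarity_to_rtf(self):
        # with all M_i = M, selection vanishes and complementarity = (RTF-1)*M
        rng = np.random.default_rng(8)
        k, m_val = 5, 12.0
        idx = [f"t{i}" for i in range(k)]
        mono = pd.Series(m_val, index=idx)
        ry = pd.Series(rng.dirichlet(np.ones(k)), index=idx)
        obs = pd.Series(rng.uniform(0.5, 6.0, k), index=idx)
        p = st.loreau_hector_partition(obs, mono, ry)
        rtf = float((obs / mono).sum())
        assert p.selection == pytest.approx(0.0, abs=1e-12)
        assert p.complementarity == pytest.approx((rtf - 1.0) * m_val, abs=1e-9)

    def test_nonpositive_monoculture_rejected(self):
        with pytest.raises(ValueError):
            st.loreau_hector_partition(
                pd.Series({"a": 1.0}), pd.Series({"a": 0.0}), pd.Series({"a": 1.0})
            )


class TestDensityRegression:
    def test_richness_effect_survives_density_adjustment(self):
        rng = np.random.default_rng(0)
        n = 60
        richness = rng.integers(2, 40, n)
        density = 10 ** rng.uniform(4, 5.5, n)  # independent of richness
        f = 2.0 + 0.4 * richness + rng.normal(0, 0.5, n)
        out = st.regression_with_density(f, richness, density)
        assert out.loc["richness", "p"] < 1e-10
        assert out.loc["log_density", "p"] > 0.001

    def test_constant_function_gives_large_p(self):
        rng = np.random.default_rng(1)
        n = 40
        out = st.regression_with_density(
            np.full(n, 3.0), rng.integers(2, 40, n), 10 ** rng.uniform(4, 5, n)
        )
        assert (out["p"] > 0.9).all()

    def test_orthogonal_design_type_two_equals_type_one(self):
        # with orthogonal predictors the type-II sum of squares equals the
        # sequential (type-I) decomposition
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(2)
        richness = np.tile([10.0, 30.0], 20)
        logd = np.repeat([4.0, 5.0], 20)  # balanced, orthogonal to richness
        f = 1 + 0.1 * richness + 0.5 * logd + rng.normal(0, 0.2, 40)
        out = st.regression_with_density(f, richness, 10**logd)
        df = pd.DataFrame({"f": f, "richness": richness, "log_density": logd})
        t1 = anova_lm(ols("f ~ richness + log_density", df).fit(), typ=1)
        assert out.loc["richness", "sum_sq"] == pytest.approx(
            t1.loc["richness", "sum_sq"], rel=1e-8)
        assert out.loc["log_density", "sum_sq"] == pytest.approx(
            t1.loc["log_density", "sum_sq"], rel=1e-8)

    def test_collinear_predictors_rejected(self):
        richness = np.linspace(2, 40, 30)
        with pytest.raises(np.linalg.LinAlgError):
            st.regression_with_density(richness * 2, richness, 10 ** (richness / 10))
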