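import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from aneumorph.errors import DesignError, ImputationError, TransformError
from aneumorph.stats import (
    EffectEstimate,
    PowerSpec,
    achieved_power,
    boxcox_transform,
    dichotomize_median,
    fit_linear,
    fit_logistic,
    impute_chained,
    log_transform,
    pool_rubin,
    required_sample_size,
    z_standardize,
)


class TestLogTransform:
    def test_e_maps_to_one(self):
        assert log_transform([np.e]).values[0] == pytest.approx(1.0)

    def test_one_maps_to_zero(self):
        assert log_transform([1.0]).values[0] == 0.0

    def test_normalizes_lognormal(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(0, 1, 2000))
        raw_p = sps.shapiro(x[:500]).pvalue
        log_p = sps.shapiro(log_transform(x).values[:500]).pvalue
        assert raw_p < 0.01 < log_p

    def test_rejects_nonpositive_with_indices(self):
        with pytest.raises(TransformError, match=r"\[1\]"):
            log_transform([2.0, -1.0, 3.0])

    def test_inverse(self):
        x = np.array([0.5, 2.0, 7.0])
        assert np.allclose(log_transform(x).inverse(), x)


class TestBoxCox:
    def test_normal_data_lambda_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(50, 2, 4000)
        tv = boxcox_transform(x)
        assert abs(tv.lam - 1.0) < 0.3

    def test_lognormal_data_lambda_near_zero(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(0, 1, 4000))
        tv = boxcox_transform(x)
        assert abs(tv.lam) < 0.1

    def test_lambda_one_closed_form(self):
        x = np.array([1.0, 2.0, 5.0])
        tv = boxcox_transform(x, lam=1.0)
        assert np.allclose(tv.values, x - 1.0)

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(0, 0.5, 100))
        tv = boxcox_transform(x)
        assert np.allclose(tv.inverse(), x)

    def test_rejects_nonpositive(self):
        with pytest.raises(TransformError):
            boxcox_transform([1.0, 0.0])


class TestZStandardize:
    def test_simple_triplet(self):
        tv = z_standardize([1.0, 2.0, 3.0])
        assert np.allclose(tv.values, [-1.0, 0.0, 1.0])

    def test_moments(self):
        rng = np.random.default_rng(4)
        tv = z_standardize(rng.gamma(2, 3, 500))
        assert abs(tv.values.mean()) < 1e-8
        assert abs(tv.values.std(ddof=1) - 1.0) < 1e-8

    @given(
        a=hst.floats(0.1, 10),
        b=hst.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 4.0, 2.5, 8.0, 0.5])
        z1 = z_standardize(x).values
        z2 = z_standardize(a * x + b).values
        assert np.allclose(z1, z2, atol=1e-8)

    def test_constant_rejected(self):
        with pytest.raises(TransformError):
            z_standardize([2.0, 2.0, 2.0])


class TestDichotomize:
    def test_even_split(self):
        assert dichotomize_median([1.0, 2.0, 3.0, 4.0]).tolist() == [0, 0, 1, 1]

    def test_tie_coded_zero(self):
        out = dichotomize_median([1.0, 2.0, 3.0])
        assert out[1] == 0  # equals the median

    def test_group1_at_most_half(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=101)
        assert dichotomize_median(x).mean() <= 0.5

    def test_constant_rejected(self):
        with pytest.raises(TransformError):
            dichotomize_median([1.0, 1.0])


class TestFitLinear:
    def test_null_effect(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=200)
        design = pd.DataFrame({"woman": np.repeat([1.0, 0.0], 100)})
        est = fit_linear(y, design)
        assert est.ci_low < 0 < est.ci_high

    def test_closed_form_on_hand_design(self):
        # normal-equations oracle on a 6-row design
        X = pd.DataFrame(
            {"woman": [1.0, 1, 1, 0, 0, 0], "age": [50.0, 60, 70, 55, 65, 75]}
        )
        y = np.array([1.0, 2.0, 2.5, 3.0, 3.5, 5.0])
        mat = np.column_stack([np.ones(6), X.to_numpy()])
        beta_hat = np.linalg.solve(mat.T @ mat, mat.T @ y)
        est = fit_linear(y, X)
        assert est.estimate == pytest.approx(beta_hat[1], abs=1e-12)

    def test_recovers_simulated_effect(self):
        rng = np.random.default_rng(7)
        n = 10_000
        woman = rng.random(n) < 0.5
        y = -0.30 * woman + rng.normal(size=n)
        est = fit_linear(y, pd.DataFrame({"woman": woman.astype(float)}))
        assert est.estimate == pytest.approx(-0.30, abs=3 * est.se)

    def test_rank_deficiency_reported(self):
        X = pd.DataFrame({"woman": [1.0, 0, 1, 0], "woman2": [1.0, 0, 1, 0]})
        with pytest.raises(DesignError, match="woman2"):
            fit_linear(np.arange(4.0), X)

    def test_missing_design_rejected(self):
        X = pd.DataFrame({"woman": [1.0, np.nan, 0.0]})
        with pytest.raises(DesignError, match="missing"):
            fit_linear(np.arange(3.0), X)


class TestFitLogistic:
    def test_matches_2x2_cross_product(self):
        # contingency-table oracle: OR = (10*8)/(5*4) = 4.0
        y = np.r_[np.ones(10), np.zeros(5), np.ones(4), np.zeros(8)]
        woman = np.r_[np.ones(15), np.zeros(12)]
        est = fit_logistic(y, pd.DataFrame({"woman": woman}))
        assert np.exp(est.estimate) == pytest.approx(4.0, abs=1e-6)

    def test_null_or_near_one(self):
        rng = np.random.default_rng(8)
        n = 5000
        y = rng.integers(0, 2, n).astype(float)
        woman = (rng.random(n) < 0.5).astype(float)
        est = fit_logistic(y, pd.DataFrame({"woman": woman}))
        point, lo, hi = est.display_scale()
        assert lo < 1.0 < hi

    def test_recovers_simulated_log_or(self):
        rng = np.random.default_rng(9)
        n = 10_000
        woman = (rng.random(n) < 0.5).astype(float)
        logit = -0.4 + np.log(2.38) * woman
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        est = fit_logistic(y, pd.DataFrame({"woman": woman}))
        assert est.estimate == pytest.approx(np.log(2.38), abs=3 * est.se)

    def test_single_class_rejected(self):
        with pytest.raises(DesignError):
            fit_logistic(np.ones(10), pd.DataFrame({"woman": np.zeros(10)}))

    def test_separation_detected(self):
        from aneumorph.errors import SeparationError

        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"woman": x}))


def _mi_cohort(n=326, rate=0.02, seed=0):
    from aneumorph.cohort import SimulationParams, generate_cohort, inject_missing

    co = generate_cohort(SimulationParams(n=n, seed=seed))
    return inject_missing(co, rate, "MCAR", seed=seed + 1)


class TestImputeChained:
    def test_zero_missing_identity(self):
        co = _mi_cohort(rate=0.0)
        out = impute_chained(co, m=3, iterations=2, seed=0)
        for t in out:
            pd.testing.assert_frame_equal(t, co)

    def test_same_seed_identical(self):
        co = _mi_cohort(rate=0.05)
        a = impute_chained(co, m=3, iterations=3, seed=5)
        b = impute_chained(co, m=3, iterations=3, seed=5)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    def test_observed_entries_untouched(self):
        co = _mi_cohort(rate=0.05)
        obs = co["smoking"].notna()
        out = impute_chained(co, m=4, iterations=3, seed=1)
        for t in out:
            assert t["smoking"].notna().all()
            assert (t.loc[obs, "smoking"] == co.loc[obs, "smoking"]).all()

    def test_imputed_frequencies_plausible(self):
        # simulation oracle: MCAR imputations track observed frequencies
        co = _mi_cohort(n=2000, rate=0.10, seed=3)
        out = impute_chained(co, m=10, iterations=5, seed=2)
        obs_freq = co["smoking"].value_counts(normalize=True)
        miss = co["smoking"].isna()
        pooled = pd.concat([t.loc[miss, "smoking"] for t in out])
        imp_freq = pooled.value_counts(normalize=True)
        for level in obs_freq.index:
            p = obs_freq[level]
            se = np.sqrt(p * (1 - p) / len(pooled))
            assert abs(imp_freq.get(level, 0.0) - p) < 4 * se, level

    def test_other_missingness_rejected(self):
        co = _mi_cohort(rate=0.02)
        co.loc[0, "age"] = np.nan
        with pytest.raises(ImputationError, match="age"):
            impute_chained(co, m=2, iterations=2, seed=0)


class TestPoolRubin:
    def _est(self, q, se, df=100.0):
        return EffectEstimate("w", "beta", q, se, q - 2 * se, q + 2 * se, df, "linear")

    def test_identical_estimates(self):
        pooled = pool_rubin([self._est(0.5, 0.1)] * 5)
        assert pooled.estimate == 0.5
        assert pooled.se == pytest.approx(0.1)

    def test_hand_arithmetic_m2(self):
        # W̄ = 0.04, B = 0.5, T = 0.04 + 1.5*0.5 = 0.79
        pooled = pool_rubin([self._est(1.0, 0.2), self._est(2.0, 0.2)])
        assert pooled.estimate == pytest.approx(1.5)
        assert pooled.se**2 == pytest.approx(0.79)

    def test_pooled_se_at_least_within(self):
        rng = np.random.default_rng(10)
        ests = [self._est(rng.normal(), 0.3) for _ in range(8)]
        pooled = pool_rubin(ests)
        assert pooled.se >= 0.3 - 1e-12

    def test_mixed_scales_rejected(self):
        bad = EffectEstimate("w", "log_or", 0.1, 0.1, 0, 0.2, np.inf, "logistic")
        with pytest.raises(ValueError, match="scales"):
            pool_rubin([self._est(0.1, 0.1), bad])

    def test_barnard_rubin_df_below_complete(self):
        pooled = pool_rubin([self._est(1.0, 0.2), self._est(2.0, 0.2)], df_com=50.0)
        assert pooled.df < 50.0


class TestSampleSize:
    def test_reported_convention_reproduces_307(self):
        assert required_sample_size(PowerSpec(8, 0.05, 0.05, 0.80)) == 307

    def test_strict_convention_minimal(self):
        # direct noncentral-F power evaluation
        spec = PowerSpec(8, 0.05, 0.05, 0.80)
        n = required_sample_size(spec, convention="strict")
        assert achieved_power(n, spec) >= 0.80
        assert achieved_power(n - 1, spec) < 0.80

    def test_monotone_in_effect_size(self):
        small = required_sample_size(PowerSpec(8, 0.05, 0.05, 0.80))
        large = required_sample_size(PowerSpec(8, 0.15, 0.05, 0.80))
        assert large < small

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PowerSpec(0, 0.05, 0.05, 0.80)
        with pytest.raises(ValueError):
            PowerSpec(8, -0.1, 0.05, 0.80)
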