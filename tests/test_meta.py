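import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pm25yll import (
    CityEffect,
    GamSpec,
    SyntheticTruth,
    fit_city_gam,
    fit_pooled_gam,
    generate_city_series,
    generate_study,
    meta_regression,
    pool_random_effects,
)
from pm25yll.gam import Z95


def _eff(city, b, se):
    return CityEffect(city, b, se, (b - Z95 * se, b + Z95 * se), "lag02", 400)


def _dl_bruteforce(bs, ses):
    """Step-by-step evaluation of the DerSimonian-Laird formulas in plain
    Python, independent of the package's vectorized implementation."""
    k = len(bs)
    w = [1.0 / s**2 for s in ses]
    sw = sum(w)
    bf = sum(wi * bi for wi, bi in zip(w, bs)) / sw
    Q = sum(wi * (bi - bf) ** 2 for wi, bi in zip(w, bs))
    if k == 1:
        tau2 = 0.0
    else:
        tau2 = max(0.0, (Q - (k - 1)) / (sw - sum(wi**2 for wi in w) / sw))
    ws = [1.0 / (s**2 + tau2) for s in ses]
    b = sum(wi * bi for wi, bi in zip(ws, bs)) / sum(ws)
    se = 1.0 / math.sqrt(sum(ws))
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return b, se, tau2, Q, I2


class TestPoolRandomEffects:
    def test_single_effect_passes_through(self):
        p = pool_random_effects([_eff("a", 0.3, 0.1)])
        assert (p.beta_per10, p.se_per10, p.tau2, p.Q) == (0.3, 0.1, 0.0, 0.0)
        assert p.k == 1

    def test_equal_se_pair_pools_to_mean(self):
        p = pool_random_effects([_eff("a", 0.2, 0.1), _eff("b", 0.6, 0.1)])
        assert p.beta_per10 == pytest.approx(0.4)

    def test_hand_evaluated_three_study_case(self):
        # betas [0.2, 0.4, 0.9], all se = 0.1:
        # Q = 26, tau2 = 24/200 = 0.12, pooled = 0.5, se = sqrt(0.13/3)
        p = pool_random_effects([_eff("a", 0.2, 0.1), _eff("b", 0.4, 0.1), _eff("c", 0.9, 0.1)])
        assert p.beta_per10 == pytest.approx(0.5, abs=1e-12)
        assert p.tau2 == pytest.approx(0.12, abs=1e-12)
        assert p.Q == pytest.approx(26.0, abs=1e-9)
        assert p.se_per10 == pytest.approx(math.sqrt(0.13 / 3), abs=1e-12)
        assert p.I2 == pytest.approx(24 / 26 * 100, abs=1e-9)

    def test_matches_statsmodels_dl(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(5)
        bs = rng.normal(0.4, 0.3, 8)
        ses = rng.uniform(0.05, 0.5, 8)
        p = pool_random_effects([_eff(f"c{i}", b, s) for i, (b, s) in enumerate(zip(bs, ses))])
        res = combine_effects(bs, ses**2, method_re="dl")
        assert p.beta_per10 == pytest.approx(float(res.mean_effect_re), abs=1e-10)
        assert p.tau2 == pytest.approx(float(res.tau2), abs=1e-10)
        assert p.se_per10 == pytest.approx(float(res.sd_eff_w_re), abs=1e-10)

    def test_homogeneous_inputs_reduce_to_fixed_effect_mean(self):
        # identical betas -> Q = 0 -> tau2 = 0 -> inverse-variance mean
        effs = [_eff("a", 0.4, 0.1), _eff("b", 0.4, 0.2), _eff("c", 0.4, 0.4)]
        p = pool_random_effects(effs)
        w = np.array([100.0, 25.0, 6.25])
        assert p.tau2 == 0.0
        assert p.beta_per10 == pytest.approx(0.4)
        assert p.se_per10 == pytest.approx(1 / math.sqrt(w.sum()))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([])

    @given(
        st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.01, 1.0)),
            min_size=2, max_size=12,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, pairs, rnd):
        effs = [_eff(f"c{i}", b, s) for i, (b, s) in enumerate(pairs)]
        shuffled = list(effs)
        rnd.shuffle(shuffled)
        p1, p2 = pool_random_effects(effs), pool_random_effects(shuffled)
        assert p1.beta_per10 == pytest.approx(p2.beta_per10, abs=1e-12)
        assert p1.tau2 == pytest.approx(p2.tau2, abs=1e-12)


class TestMetaRegression:
    def _effects_linear(self, k=10, slope=0.5, se=0.1):
        x = np.linspace(0, 10, k)
        return (
            [_eff(f"c{i}", 0.2 + slope * xi, se) for i, xi in enumerate(x)],
            {f"c{i}": float(xi) for i, xi in enumerate(x)},
        )

    def test_exact_linear_relationship_recovered(self):
        # equal ses: WLS reduces to OLS; slope per IQR = slope * IQR exactly
        effs, cov = self._effects_linear(slope=0.5)
        x = np.array(list(cov.values()))
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        r = meta_regression(effs, cov, "xvar")
        assert r.iqr == pytest.approx(iqr)
        assert r.slope_per_iqr == pytest.approx(0.5 * iqr, rel=1e-9)

    def test_null_covariate_slope_small(self):
        rng = np.random.default_rng(17)
        effs = [_eff(f"c{i}", float(rng.normal(0.4, 0.05)), 0.25) for i in range(40)]
        cov = {f"c{i}": float(rng.normal(0, 1)) for i in range(40)}
        r = meta_regression(effs, cov, "noise")
        assert abs(r.slope_per_iqr) < 3 * r.se
        assert r.p_value > 0.01

    def test_interaction_of_independent_nulls_not_significant(self):
        rng = np.random.default_rng(23)
        effs = [_eff(f"c{i}", float(rng.normal(0.4, 0.05)), 0.25) for i in range(40)]
        cov1 = {f"c{i}": float(rng.normal(50, 10)) for i in range(40)}
        cov2 = {f"c{i}": float(rng.lognormal(7, 1)) for i in range(40)}
        r = meta_regression(effs, cov1, "a", interaction_with=cov2, interaction_name="b")
        assert r.interaction_p is not None and r.interaction_p > 0.05

    def test_constant_covariate_rejected(self):
        effs, _ = self._effects_linear()
        with pytest.raises(ValueError, match="constant"):
            meta_regression(effs, {e.city_id: 1.0 for e in effs}, "const")

    def test_too_few_cities_rejected(self):
        effs, cov = self._effects_linear(k=2)
        with pytest.raises(ValueError, match="k >= 3"):
            meta_regression(effs, cov, "xvar")


class TestPooledGam:
    def _noiseless_pair(self, n=500):
        from pm25yll import CityMeta

        truth = SyntheticTruth(beta_per10=0.43, trend_amplitude=0.0,
                               temp_effect_amplitude=0.0, yll_noise_sd=0.0, seed=12)
        metas = {}
        series = []
        for i, cid in enumerate(("A1", "A2")):
            meta = CityMeta(cid, "East", 118.0 + i, 30.0 + i, {})
            s, _ = generate_city_series(truth, meta, n, seed=12, mean_only=True)
            s.city_id = cid
            series.append(s)
            metas[cid] = meta
        return series, metas

    def test_city_intercepts_noiseless_recovery(self):
        series, metas = self._noiseless_pair()
        est = fit_pooled_gam(series, metas, mode="city_intercepts")
        assert abs(est.beta_per10 - 0.43) < 1e-6
        assert est.mode == "city_intercepts" and est.k == 2

    def test_spatial_mode_runs_with_distinct_coordinates(self):
        # needs enough distinct city locations to support the 3+3 df
        # longitude/latitude smooths (city-level terms are limited to k-1)
        dataset, _ = generate_study({"East": 8}, n_days=400, seed=19)
        est = fit_pooled_gam(dataset.series, dataset.meta_by_id, mode="spatial")
        assert np.isfinite(est.se_per10) and est.se_per10 > 0

    def test_spatial_mode_single_location_rejected(self):
        series, metas = self._noiseless_pair()
        from pm25yll import CityMeta

        same = {cid: CityMeta(cid, "East", 118.0, 30.0, {}) for cid in metas}
        with pytest.raises(ValueError, match="distinct"):
            fit_pooled_gam(series, same, mode="spatial")

    def test_one_stage_agrees_with_two_stage_within_error(self, small_study, small_effects):
        dataset, _ = small_study
        pooled = pool_random_effects(small_effects)
        est = fit_pooled_gam(dataset.series, dataset.meta_by_id, mode="city_intercepts")
        assert abs(est.beta_per10 - pooled.beta_per10) < 2 * pooled.se_per10


@given(
    st.lists(
        st.tuples(st.floats(-1, 1), st.floats(0.02, 0.8)),
        min_size=1, max_size=10,
    )
)
def test_dl_agrees_with_bruteforce_on_random_inputs(pairs):
    bs = [b for b, _ in pairs]
    ses = [s for _, s in pairs]
    p = pool_random_effects([_eff(f"c{i}", b, s) for i, (b, s) in enumerate(pairs)])
    b, se, tau2, Q, I2 = _dl_bruteforce(bs, ses)
    assert p.beta_per10 == pytest.approx(b, abs=1e-10)
    assert p.se_per10 == pytest.approx(se, abs=1e-10)
    assert p.tau2 == pytest.approx(tau2, abs=1e-10)
    assert p.Q == pytest.approx(Q, abs=1e-10)
    assert p.I2 == pytest.approx(I2, abs=1e-8)
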