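"""Detrending, moving-window correlations, trend tests, uncertainty."""

import numpy as np
import pytest
from scipy import stats

import edhwheat as e
from edhwheat.sensitivity import (
    METHODS,
    _pearson_windows_grid,
    grid_trend_field,
)


class TestDetrend:
    def test_pure_linear_to_zeros(self):
        t = np.arange(30, dtype=float)
        np.testing.assert_allclose(e.detrend_linear(3.0 * t + 2.0), 0.0, atol=1e-10)

    def test_residual_slope_and_mean_zero(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=59) + 0.1 * np.arange(59)
        r = e.detrend_linear(y)
        assert abs(r.mean()) < 1e-10
        assert abs(stats.linregress(np.arange(59.0), r).slope) < 1e-10

    def test_sinusoid_on_trend(self):
        t = np.arange(59, dtype=float)
        s = np.sin(t)
        resid = e.detrend_linear(2.0 * t + s)
        # residuals equal the sinusoid minus its own OLS line
        np.testing.assert_allclose(resid, e.detrend_linear(s), atol=1e-10)

    def test_constant_series_to_zeros(self):
        np.testing.assert_allclose(e.detrend_linear(np.full(10, 4.2)), 0.0, atol=1e-12)


class TestMovingWindowCorrelation:
    def test_perfect_linear_coupling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=59)
        for method in METHODS:
            r = e.moving_window_correlation(x, 2.0 * x + 1.0, window=20, method=method)
            assert r.shape == (40,)
            np.testing.assert_allclose(r, 1.0, atol=1e-12)
            r = e.moving_window_correlation(x, -x, window=20, method=method)
            np.testing.assert_allclose(r, -1.0, atol=1e-12)

    @pytest.mark.parametrize("method,direct", [
        ("pearson", lambda a, b: stats.pearsonr(a, b).statistic),
        ("kendall", lambda a, b: stats.kendalltau(a, b).statistic),
        ("spearman", lambda a, b: stats.spearmanr(a, b).statistic),
    ])
    def test_matches_direct_sliced_computation(self, method, direct):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.normal(size=59)
            y = rng.normal(size=59)
            r = e.moving_window_correlation(x, y, window=20, method=method)
            for k in (0, 17, 39):
                assert r[k] == pytest.approx(direct(x[k:k+20], y[k:k+20]), abs=1e-12)

    def test_hand_series_two_windows(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=21), rng.normal(size=21)
        r = e.moving_window_correlation(x, y, window=20)
        assert r.size == 2
        assert r[0] == pytest.approx(np.corrcoef(x[:20], y[:20])[0, 1])
        assert r[1] == pytest.approx(np.corrcoef(x[1:], y[1:])[0, 1])

    def test_null_coupling_mean_near_zero(self):
        rng = np.random.default_rng(99)
        means = []
        for _ in range(200):
            x, y = rng.normal(size=40), rng.normal(size=40)
            means.append(np.nanmean(e.moving_window_correlation(x, y, window=20)))
        assert abs(np.mean(means)) < 3.0 / np.sqrt(20)

    def test_zero_variance_window_missing(self):
        x = np.zeros(25)
        y = np.arange(25.0)
        r = e.moving_window_correlation(x, y, window=20)
        assert np.isnan(r).all()

    def test_vectorized_grid_equals_series_path(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(3, 4, 40))
        y = rng.normal(size=(3, 4, 40))
        grid = _pearson_windows_grid(x, y, 20)
        for i in range(3):
            for j in range(4):
                np.testing.assert_allclose(
                    grid[i, j],
                    e.moving_window_correlation(x[i, j], y[i, j], window=20),
                    atol=1e-10,
                )

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            e.moving_window_correlation(np.arange(10.0), np.arange(10.0), window=2)


class TestSensitivityField:
    def test_injected_coupling_recovered(self, small_suite):
        _, edh, suite = small_suite
        # yield is built with negative dry-heat betas: R(index, yield) < 0
        field = e.sensitivity_field(edh, suite["S2"]["yield"].rename("yield"))
        assert field["r_hc"].shape == (8, 8, 40)
        assert np.nanmean(field["r_hc"].values) < -0.3
        assert np.nanmean(field["r_dc"].values) < -0.3
        assert np.all(np.abs(field["r_cdhc"].values[~np.isnan(field["r_cdhc"].values)]) <= 1.0)

    def test_masked_response_propagates(self, small_suite):
        _, edh, suite = small_suite
        y = suite["S2"]["yield"].copy(deep=True)
        y[0, 0, 30] = np.nan
        field = e.sensitivity_field(edh, y.rename("yield"))
        assert np.isnan(field["r_hc"].values[0, 0]).all()
        assert not np.isnan(field["r_hc"].values[1, 1]).any()


class TestTrends:
    def test_constant_series_no_trend(self):
        tr = e.grid_sensitivity_trend(np.full(40, 0.3))
        assert tr["slope"] == 0.0 and tr["p_value"] == 1.0 and not tr["significant"]

    def test_injected_drift_recovered(self):
        rng = np.random.default_rng(8)
        drift = 0.005
        r = 0.2 + drift * np.arange(40) + rng.normal(0, 0.01, 40)
        tr = e.grid_sensitivity_trend(r)
        assert tr["slope"] == pytest.approx(drift, abs=0.002)
        assert tr["significant"]

    def test_grid_trend_field_matches_cellwise(self, small_suite):
        _, edh, suite = small_suite
        field = e.sensitivity_field(edh, suite["S2"]["yield"].rename("yield"))
        sub = field.isel(lat=slice(0, 2), lon=slice(0, 2))
        tf = grid_trend_field(sub)
        tr = e.grid_sensitivity_trend(
            sub["r_hc"].values[0, 1], sub["window_end_year"].values.astype(float)
        )
        assert tf["r_hc_slope"].values[0, 1] == pytest.approx(tr["slope"])
        assert tf["r_hc_p"].values[0, 1] == pytest.approx(tr["p_value"])


class TestMannKendall:
    def test_monotone_series(self):
        n = 30
        tr = e.mann_kendall_trend(np.arange(n, dtype=float))
        assert tr["s_statistic"] == n * (n - 1) // 2
        assert tr["p_value"] < 1e-6
        assert tr["significant"]

    def test_all_equal_series(self):
        tr = e.mann_kendall_trend(np.full(20, 3.0))
        assert tr["s_statistic"] == 0
        assert tr["p_value"] == 1.0

    def test_agrees_with_kendalltau_p(self):
        # scipy's tau test with normal approximation is the independent
        # reference for the tie-free case
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.normal(size=40)
            ours = e.mann_kendall_trend(x)
            ref = stats.kendalltau(np.arange(40), x, method="asymptotic")
            assert ours["p_value"] == pytest.approx(ref.pvalue, abs=0.02)

    def test_type_one_error_small_sample(self):
        # quick null-calibration check; the full 5000-rep version runs in
        # the acceptance suite
        rng = np.random.default_rng(123)
        rej = np.mean([
            e.mann_kendall_trend(rng.normal(size=40))["significant"]
            for _ in range(500)
        ])
        assert 0.02 <= rej <= 0.08

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            e.mann_kendall_trend([1.0, 2.0])


class TestUncertainty:
    def test_identical_fields_zero_spread(self, small_suite):
        _, edh, suite = small_suite
        f = e.sensitivity_field(edh, suite["S2"]["yield"].rename("yield"))
        u = e.uncertainty_across_combinations([f, f, f])
        assert np.nanmax(u["r_hc_sd"].values) < 1e-12
        assert np.nanmax(u["r_hc_se"].values) < 1e-12

    def test_hand_arithmetic_two_fields(self, small_suite):
        _, edh, suite = small_suite
        f1 = e.sensitivity_field(edh, suite["S2"]["yield"].rename("yield"))
        f2 = f1.copy(deep=True)
        f1["r_hc"][:] = 0.1
        f2["r_hc"][:] = 0.3
        u = e.uncertainty_across_combinations([f1, f2])
        assert np.allclose(u["r_hc_mean"].values, 0.2)
        assert np.allclose(u["r_hc_sd"].values, np.sqrt(0.02), rtol=1e-10)
        assert np.allclose(u["r_hc_se"].values, 0.1, rtol=1e-10)

    def test_se_is_sd_over_sqrt_n(self, small_suite):
        _, edh, suite = small_suite
        rng = np.random.default_rng(2)
        base = e.sensitivity_field(edh, suite["S2"]["yield"].rename("yield"))
        fields = []
        for _ in range(9):
            f = base.copy(deep=True)
            f["r_hc"].values[:] = rng.uniform(-1, 1, f["r_hc"].shape)
            fields.append(f)
        u = e.uncertainty_across_combinations(fields)
        np.testing.assert_allclose(
            u["r_hc_se"].values, u["r_hc_sd"].values / 3.0, rtol=1e-12
        )


class TestRegionalSummary:
    def test_all_positive_field(self, small_suite):
        _, edh, suite = small_suite
        f = e.sensitivity_field(edh, suite["S2"]["yield"].rename("yield"))
        f["r_hc"][:] = 0.5
        s = e.regional_summary(f)
        np.testing.assert_allclose(s["r_hc_median"].values, 0.5)
        np.testing.assert_allclose(s["r_hc_pos_share"].values, 1.0)
        np.testing.assert_allclose(s["r_hc_neg_share"].values, 0.0)

    def test_random_field_matches_brute_force(self, small_suite):
        _, edh, suite = small_suite
        f = e.sensitivity_field(edh, suite["S2"]["yield"].rename("yield"))
        rng = np.random.default_rng(4)
        f["r_dc"].values[:] = rng.uniform(-1, 1, f["r_dc"].shape)
        s = e.regional_summary(f)
        flat = f["r_dc"].values.reshape(-1, 40)
        np.testing.assert_allclose(s["r_dc_median"].values, np.median(flat, axis=0))
        np.testing.assert_allclose(
            s["r_dc_pos_share"].values, np.mean(flat > 0, axis=0)
        )

    def test_mask_restricts_cells(self, small_suite):
        _, edh, suite = small_suite
        f = e.sensitivity_field(edh, suite["S2"]["yield"].rename("yield"))
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True
        s = e.regional_summary(f, mask=mask)
        np.testing.assert_allclose(
            s["r_hc_median"].values, f["r_hc"].values[0, 0], atol=1e-12
        )
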