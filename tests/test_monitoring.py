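"""Growth analytics: extraction, rates, normalization, correlation, drift."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eismon as em
from eismon.monitoring import DEFAULT_WINDOWS


def _series_from_modulus(times, modulus_rows, freqs=None):
    """Build a series whose spectra have prescribed |Z| (purely real)."""
    freqs = np.asarray([8.0, 12.5] if freqs is None else freqs, float)
    spectra = [em.Spectrum(freqs, np.asarray(row, float) + 0j)
               for row in modulus_rows]
    return em.MonitoringSeries(times, spectra)


class TestImpedanceAt:
    def test_on_grid_point_no_interpolation(self):
        series = _series_from_modulus([0.0], [[1000.0, 800.0]])
        z = em.impedance_at(series, 8.0)
        assert z.iloc[0] == 1000.0

    def test_log_log_interpolation_between_brackets(self):
        # 10 Hz is the exact log midpoint of 8 and 12.5 Hz, so the modulus
        # interpolates to the geometric mean sqrt(1000 * 800) = 894.43
        series = _series_from_modulus([0.0], [[1000.0, 800.0]])
        z = em.impedance_at(series, 10.0)
        assert z.iloc[0] == pytest.approx(np.sqrt(1000.0 * 800.0), rel=1e-9)

    def test_extraction_matches_generator_truth_within_noise(self):
        scenario = em.scenario_preset("auxin_rich", seed=5,
                                      spectrum_interval=24.0)
        series = em.simulate_series(scenario)
        z = em.impedance_at(series, 10.0)
        for t, val in z.items():
            truth = abs(em.circuit_impedance(10.0, em.params_at(scenario, t)))
            assert val == pytest.approx(truth, rel=0.05)

    def test_out_of_range_names_timepoint(self):
        series = _series_from_modulus([7.0], [[1000.0, 800.0]])
        with pytest.raises(ValueError, match="timepoint 7"):
            em.impedance_at(series, 100.0)


class TestEstimateRate:
    def test_exact_line_recovers_slope(self):
        t = np.arange(0, 97, 24.0)
        values = pd.Series(20.0 + 12.8e-3 * t, index=t)  # 12.8 ug/h in mg
        est = em.estimate_rate(values, (0, 96), model="linear")
        assert est.rate * 1e3 == pytest.approx(12.8)
        assert est.r_squared == pytest.approx(1.0)

    def test_exact_exponential_recovers_rate_constant(self):
        t = np.arange(0, 100.0)
        values = pd.Series(100.0 * np.exp(0.02 * t), index=t)
        est = em.estimate_rate(values, model="exponential")
        assert est.rate_constant == pytest.approx(0.02, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0)
        # window-mean slope of the fitted exponential
        expected_slope = (values.iloc[-1] - values.iloc[0]) / (t[-1] - t[0])
        assert est.rate == pytest.approx(expected_slope, rel=1e-9)

    def test_noisy_line_slope_within_confidence_interval(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 97.0)
        truth = 5.0
        y = 100 + truth * t
        noise = 0.05 * np.ptp(y)
        values = pd.Series(y + rng.normal(0, noise, t.size), index=t)
        est = em.estimate_rate(values, (0, 96), model="linear")
        assert abs(est.rate - truth) < 1.96 * est.stderr

    def test_per_day_conversion(self):
        t = np.arange(5.0)
        est = em.estimate_rate(pd.Series(2.0 * t, index=t), model="linear")
        assert est.rate_per_day == pytest.approx(48.0)

    def test_insufficient_points_and_nonpositive_exponential(self):
        t = np.arange(5.0)
        with pytest.raises(ValueError, match=">= 3 points"):
            em.estimate_rate(pd.Series(t, index=t), (0, 1))
        with pytest.raises(ValueError, match="positive"):
            em.estimate_rate(pd.Series([1.0, -1.0, 2.0, 3.0, 4.0], index=t),
                             model="exponential")


class TestMinMaxNormalize:
    def test_basic_example(self):
        np.testing.assert_allclose(em.minmax_normalize([0.0, 5.0, 10.0]),
                                   [0.0, 0.5, 1.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=20),
           st.floats(0.1, 10.0), st.floats(-100.0, 100.0))
    def test_affine_invariance(self, values, a, b):
        arr = np.asarray(values)
        if np.ptp(arr) < 1e-6:
            return
        direct = em.minmax_normalize(arr)
        shifted = em.minmax_normalize(a * arr + b)
        np.testing.assert_allclose(direct, shifted, atol=1e-6)

    def test_attains_bounds_and_preserves_ranks(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=50)
        out = em.minmax_normalize(arr)
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_array_equal(np.argsort(out), np.argsort(arr))

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            em.minmax_normalize([2.0, 2.0, 2.0])


class TestMassImpedanceCorrelation:
    def _linear_series(self, mass_slope=1.0, z_slope=10.0):
        t = np.arange(0, 169.0)
        freqs = np.array([5.0, 10.0, 20.0])
        spectra = [em.Spectrum(freqs,
                               np.full(3, 1000.0 + z_slope * ti) + 0j)
                   for ti in t]
        mass_t = np.arange(0, 169.0, 24.0)
        masses = pd.DataFrame({"time_h": mass_t,
                               "mass_mg": 20.0 + mass_slope * mass_t})
        return em.MonitoringSeries(t, spectra, masses=masses)

    def test_perfectly_linear_trends_give_r_one(self):
        corr = em.mass_impedance_correlation(self._linear_series(), 10.0)
        assert corr.pearson_r == pytest.approx(1.0)
        assert corr.n_points == 8

    def test_opposite_trends_give_r_minus_one(self):
        corr = em.mass_impedance_correlation(
            self._linear_series(z_slope=-2.0), 10.0)
        assert corr.pearson_r == pytest.approx(-1.0)

    def test_synthetic_scenario_correlates_strongly(self):
        scenario = em.scenario_preset("auxin_rich", seed=1, mass_sigma=0.3)
        series = em.simulate_series(scenario)
        corr = em.mass_impedance_correlation(series, 10.0)
        assert corr.pearson_r > 0.9

    def test_pearson_invariant_under_normalization(self):
        # min-max is affine, so r on raw and normalized data agree
        from scipy.stats import pearsonr
        scenario = em.scenario_preset("auxin_rich", seed=8)
        series = em.simulate_series(scenario)
        corr = em.mass_impedance_correlation(series, 10.0)
        raw_r, _ = pearsonr(corr.normalized_x, corr.normalized_y)
        assert corr.pearson_r == pytest.approx(raw_r)
        assert abs(corr.pearson_r) <= 1.0

    def test_too_few_common_timepoints(self):
        series = self._linear_series()
        series.masses = series.masses.iloc[:2]
        with pytest.raises(ValueError, match=">= 3"):
            em.mass_impedance_correlation(series, 10.0)


class TestRelativeChange:
    @pytest.mark.parametrize("initial,final,expected", [
        (13.32, 9.93, 25.45),   # capacitance decline, auxin-rich
        (10.15, 8.73, 13.99),   # capacitance decline, auxin-free
        (3.0, 1.8, 40.0),       # Rct rate reduction
        (2.5, 2.1, 16.0),       # impedance rate reduction
    ])
    def test_reported_percentages(self, initial, final, expected):
        assert em.relative_change(initial, final) == pytest.approx(expected,
                                                                   abs=0.005)

    def test_no_change_is_zero(self):
        assert em.relative_change(7.7, 7.7) == 0.0

    def test_zero_initial_rejected(self):
        with pytest.raises(ValueError):
            em.relative_change(0.0, 1.0)


class TestImpedanceCdlRegression:
    def test_cdl_only_variation_is_linear(self):
        # freeze Rsol and Rct; only the capacitance declines
        scenario = em.scenario_preset(
            "auxin_rich", seed=9, noise_alpha=0.0, spectrum_interval=12.0,
            rsol_drift=0.0, rct_dip_depth=0.0, rct_rate=0.0)
        series = em.simulate_series(scenario)
        em.fit_series(series)
        reg = em.impedance_cdl_regression(series, 10.0)
        assert reg.r_squared > 0.99
        assert reg.slope < 0  # |Z| rises as Cdl falls

    def test_requires_fits(self, short_rich_series):
        _, series = short_rich_series
        series.fits = None
        with pytest.raises(ValueError, match="fit_series"):
            em.impedance_cdl_regression(series, 10.0)

    def test_constant_cdl_degenerate(self):
        scenario = em.scenario_preset(
            "medium_only", seed=3, noise_alpha=0.0, spectrum_interval=24.0)
        series = em.simulate_series(scenario)
        em.fit_series(series)
        reg = em.impedance_cdl_regression(series, 10.0)
        assert np.isnan(reg.slope)
        assert reg.r_squared == 0.0


class TestControlDriftCheck:
    def test_constant_control_passes(self):
        t = np.arange(0, 169.0)
        series = _series_from_modulus(t, [[1000.0, 800.0]] * t.size)
        drift = em.control_drift_check(series, 8.0)
        assert drift.passed
        assert drift.max_abs_deviation == 0.0

    def test_one_percent_per_day_drift_fails_over_seven_days(self):
        t = np.arange(0, 169.0)
        z0 = 1000.0
        rows = [[z0 * (1 + 0.01 * ti / 24.0)] * 2 for ti in t]
        series = _series_from_modulus(t, rows)
        drift = em.control_drift_check(series, 8.0, threshold=0.05)
        assert not drift.passed  # 7% cumulative drift exceeds 5%

    def test_pure_noise_passes(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 169.0)
        rows = [[1000.0 * (1 + rng.normal(0, 0.005))] * 2 for ti in t]
        series = _series_from_modulus(t, rows)
        drift = em.control_drift_check(series, 8.0)
        assert drift.passed


def test_default_windows_match_study_protocol():
    assert DEFAULT_WINDOWS["impedance"] == (24.0, 144.0)
    assert DEFAULT_WINDOWS["mass"] == (0.0, 96.0)
    assert DEFAULT_WINDOWS["rct_auxin_rich"] == (72.0, 144.0)
    assert DEFAULT_WINDOWS["rct_auxin_free"] == (96.0, 168.0)
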