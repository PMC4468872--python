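import numpy as np
import pytest

from fibrilmap.periodicity import (
    Correlogram,
    analyze_profile,
    autocorrelate,
    average_correlograms,
    classify_periodic,
    cross_correlate,
    detect_peak_ladder,
    refine_first_peak,
)


def brute_force_autocorr(y, nlag, mode="unbiased"):
    """Direct O(n^2) lag sums, independent of the vectorized path."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = y - y.mean()
    var = np.mean(x**2)
    out = np.empty(nlag + 1)
    for k in range(nlag + 1):
        s = 0.0
        for i in range(n - k):
            s += x[i] * x[i + k]
        denom = (n - k) if mode == "unbiased" else n
        out[k] = s / denom / var
    return out


def delta_comb(n_periods=10, period_bins=38, bin_width=2.5):
    y = np.zeros(n_periods * period_bins)
    y[::period_bins] = 1.0
    return y


class TestAutocorrelate:
    def test_matches_brute_force(self, rng, profile_factory):
        y = rng.random(200)
        prof = profile_factory(y)
        corr = autocorrelate(prof, max_lag_nm=150.0)
        nlag = len(corr.lags) - 1
        np.testing.assert_allclose(
            corr.values, brute_force_autocorr(y, nlag), atol=1e-10
        )

    def test_biased_mode_matches_brute_force(self, rng, profile_factory):
        y = rng.random(150)
        corr = autocorrelate(profile_factory(y), max_lag_nm=100.0, mode="biased")
        nlag = len(corr.lags) - 1
        np.testing.assert_allclose(
            corr.values, brute_force_autocorr(y, nlag, mode="biased"), atol=1e-10
        )

    def test_unit_at_lag_zero(self, rng, profile_factory):
        corr = autocorrelate(profile_factory(rng.random(100)), max_lag_nm=50.0)
        assert corr.values[0] == pytest.approx(1.0)

    def test_comb_maxima_at_period_multiples(self, profile_factory):
        prof = profile_factory(delta_comb())  # period 95 nm at 2.5 nm bins
        corr = autocorrelate(prof, max_lag_nm=400.0)
        peaks = detect_peak_ladder(corr, min_lag_nm=30.0)
        np.testing.assert_allclose(peaks[:4], [95, 190, 285, 380], atol=2.5)

    def test_constant_profile_flagged(self, profile_factory):
        corr = autocorrelate(profile_factory(np.full(100, 3.0)), max_lag_nm=50.0)
        assert corr.zero_variance
        assert np.all(corr.values[1:] == 0)

    def test_symmetric_under_reversal(self, rng, profile_factory):
        y = rng.random(120)
        a = autocorrelate(profile_factory(y), max_lag_nm=80.0)
        b = autocorrelate(profile_factory(y[::-1]), max_lag_nm=80.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_affine_intensity_invariance(self, rng, profile_factory):
        y = rng.random(120)
        a = autocorrelate(profile_factory(y), max_lag_nm=80.0)
        b = autocorrelate(profile_factory(3.5 * y + 2.0), max_lag_nm=80.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestPeakLadder:
    def test_monotone_decay_no_peaks(self, profile_factory):
        lags = 2.5 * np.arange(100)
        corr = Correlogram(lags, np.exp(-lags / 50.0))
        assert len(detect_peak_ladder(corr)) == 0

    def test_two_component_comb_matches_scan(self, profile_factory):
        y = np.zeros(500)
        y[::38] += 1.0  # 95 nm at 2.5 nm bins
        y[::55] += 1.0  # 137.5 nm
        corr = autocorrelate(profile_factory(y), max_lag_nm=400.0)
        peaks = detect_peak_ladder(corr, min_lag_nm=30.0, prominence=0.0)
        mask = corr.lags >= 30.0
        vals, lags = corr.values[mask], corr.lags[mask]
        scan = lags[
            np.flatnonzero(
                (vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])
            ) + 1
        ]
        np.testing.assert_allclose(peaks, scan)


class TestClassify:
    def test_perfect_ladder_is_periodic(self):
        ok, cv = classify_periodic(np.array([95.0, 190.0, 285.0, 380.0]))
        assert ok and cv == pytest.approx(0.0)

    def test_three_peaks_insufficient(self):
        ok, _ = classify_periodic(np.array([95.0, 150.0, 320.0]))
        assert not ok

    def test_irregular_spacing_rejected(self):
        ok, cv = classify_periodic(np.array([95.0, 160.0, 285.0, 400.0]))
        assert not ok

    def test_regular_but_offset_ladder_rejected(self):
        # equally spaced but not harmonics of the spacing
        ok, _ = classify_periodic(np.array([50.0, 145.0, 240.0, 335.0]))
        assert not ok


class TestRefine:
    def test_symmetric_vertex(self):
        corr = Correlogram(np.array([90.0, 95.0, 100.0]), np.array([0.5, 1.0, 0.5]))
        assert refine_first_peak(corr, 95.0) == pytest.approx(95.0)

    def test_asymmetric_vertex_closed_form(self):
        corr = Correlogram(np.array([90.0, 95.0, 100.0]), np.array([0.4, 1.0, 0.6]))
        # vertex = 95 + (5/2)(0.4-0.6)/(0.4-2+0.6) = 95.5
        assert refine_first_peak(corr, 95.0) == pytest.approx(95.5)

    def test_non_concave_falls_back(self):
        corr = Correlogram(np.array([90.0, 95.0, 100.0]), np.array([0.2, 0.5, 0.9]))
        with pytest.warns(UserWarning, match="non-concave"):
            assert refine_first_peak(corr, 95.0) == pytest.approx(95.0)

    def test_edge_lag_rejected(self):
        corr = Correlogram(np.array([90.0, 95.0, 100.0]), np.array([0.5, 1.0, 0.5]))
        with pytest.raises(ValueError):
            refine_first_peak(corr, 90.0)


class TestCrossCorrelate:
    def periodic_profile(self, profile_factory, phase_nm=0.0, noise=None):
        bw = 2.5
        x = bw * np.arange(400) + bw / 2
        y = 1 + np.cos(2 * np.pi * (x - phase_nm) / 95.0)
        if noise is not None:
            y = y + noise
        return profile_factory(y)

    def test_self_correlation_peaks_at_zero(self, profile_factory):
        a = self.periodic_profile(profile_factory)
        cc = cross_correlate(a, a, max_lag_nm=200.0)
        i_max = int(np.argmax(cc.values))
        assert cc.lags[i_max] == pytest.approx(0.0)
        assert cc.values[i_max] == pytest.approx(1.0, abs=1e-9)

    def test_half_period_shift_anticorrelated(self, profile_factory):
        a = self.periodic_profile(profile_factory)
        b = self.periodic_profile(profile_factory, phase_nm=47.5)
        cc = cross_correlate(a, b, max_lag_nm=200.0)
        i0 = int(np.argmin(np.abs(cc.lags)))
        assert cc.values[i0] < -0.9
        assert abs(abs(cc.lags[np.argmax(cc.values)]) - 47.5) <= 2.5

    def test_in_phase_with_independent_noise(self, rng, profile_factory):
        a = self.periodic_profile(profile_factory, noise=0.3 * rng.random(400))
        b = self.periodic_profile(profile_factory, noise=0.3 * rng.random(400))
        cc = cross_correlate(a, b, max_lag_nm=200.0)
        assert cc.lags[np.argmax(cc.values)] == pytest.approx(0.0)

    def test_binning_mismatch_rejected(self, profile_factory):
        a = profile_factory(np.random.default_rng(0).random(100), bin_width=2.5)
        b = profile_factory(np.random.default_rng(0).random(100), bin_width=5.0)
        with pytest.raises(ValueError, match="binning"):
            cross_correlate(a, b)


class TestAverage:
    def test_identity(self, rng):
        lags = 2.5 * np.arange(50)
        c = Correlogram(lags, rng.random(50))
        avg = average_correlograms([c, c, c])
        np.testing.assert_allclose(avg.values, c.values)
        assert avg.n_averaged == 3

    def test_cancellation(self):
        lags = 2.5 * np.arange(20)
        plus = Correlogram(lags, np.full(20, 0.4))
        minus = Correlogram(lags, np.full(20, -0.4))
        avg = average_correlograms([plus, minus, plus, minus])
        np.testing.assert_allclose(avg.values, 0.0, atol=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_correlograms([])


class TestAnalyzeProfile:
    def test_comb_classified_periodic_and_refined(self, profile_factory):
        res = analyze_profile(profile_factory(delta_comb()))
        assert res.is_periodic
        assert res.L_hat == pytest.approx(95.0, abs=2.5)

    def test_flat_profile_not_periodic(self, profile_factory):
        res = analyze_profile(profile_factory(np.full(400, 2.0)))
        assert not res.is_periodic
        assert res.L_hat is None
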