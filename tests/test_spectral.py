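import numpy as np
import pytest

import ambubrs as ab
from ambubrs.spectral import band_bins


def dft_welch_oracle(x, y, fs=4.0, nperseg=120, noverlap=60):
    """Brute-force cross-spectral oracle: raw segment periodograms by direct
    DFT, averaged. Independent of scipy's Welch implementation (only
    ``np.fft`` is used); periodic Hann taper, segment-mean removal,
    one-sided density scaling."""
    n = np.arange(nperseg)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * n / nperseg)
    step = nperseg - noverlap
    starts = range(0, len(x) - nperseg + 1, step)
    pxx = pyy = pxy = 0.0
    for s in starts:
        xs = x[s : s + nperseg] - np.mean(x[s : s + nperseg])
        ys = y[s : s + nperseg] - np.mean(y[s : s + nperseg])
        X = np.fft.rfft(xs * w)
        Y = np.fft.rfft(ys * w)
        pxx = pxx + np.abs(X) ** 2
        pyy = pyy + np.abs(Y) ** 2
        pxy = pxy + np.conj(X) * Y
    k = len(list(starts))
    scale = 1.0 / (fs * np.sum(w**2))
    sided = np.full(nperseg // 2 + 1, 2.0)
    sided[0] = 1.0
    if nperseg % 2 == 0:
        sided[-1] = 1.0
    f = np.fft.rfftfreq(nperseg, 1.0 / fs)
    pxx, pyy, pxy = (p / k * scale * sided for p in (pxx, pyy, pxy))
    return f, pxx, pyy, pxy


class TestUniformResampling:
    def test_identity_on_grid_aligned_beats(self):
        t = np.arange(0.0, 40.0, 0.25)
        v = np.sin(t)
        grid, series = ab.to_uniform_series(t, v, detrend=False)
        np.testing.assert_allclose(series, np.sin(grid), atol=1e-12)

    def test_linear_series_detrends_to_zero(self):
        t = np.cumsum(np.full(100, 0.9))
        grid, series = ab.to_uniform_series(t, 3.0 + 0.5 * t)
        assert np.allclose(series, 0.0, atol=1e-9)

    def test_sinusoidal_beat_series_peaks_at_its_frequency(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.uniform(0.8, 1.2, size=600))
        v = np.sin(2 * np.pi * 0.1 * t)
        grid, series = ab.to_uniform_series(t, v)
        spec = np.abs(np.fft.rfft(series))
        f = np.fft.rfftfreq(series.size, 0.25)
        assert abs(f[np.argmax(spec)] - 0.1) < 0.01

    def test_long_gap_rejects_window(self):
        t = np.concatenate([np.arange(0.0, 30.0), np.arange(40.0, 70.0)])
        with pytest.raises(ab.WindowRejected, match="gap"):
            ab.to_uniform_series(t, np.ones_like(t))

    def test_nan_values_bridged_when_gap_small(self):
        t = np.arange(0.0, 60.0)
        v = np.sin(0.3 * t)
        v[10:13] = np.nan
        grid, series = ab.to_uniform_series(t, v, detrend=False)
        assert np.isfinite(series).all()

    def test_too_short_window_rejected(self):
        with pytest.raises(ab.WindowRejected, match="too_short"):
            ab.to_uniform_series([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])


class TestTransferEstimate:
    def test_matches_direct_dft_oracle_to_machine_precision(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=480)
        y = np.convolve(rng.normal(size=480), [0.4, 0.3, 0.2], mode="same")
        est = ab.estimate_transfer(x, y)
        f, pxx, pyy, pxy = dft_welch_oracle(x, y)
        np.testing.assert_allclose(est.f, f, rtol=1e-12)
        np.testing.assert_allclose(est.Pxx, pxx, rtol=1e-10)
        np.testing.assert_allclose(est.Pyy, pyy, rtol=1e-10)
        np.testing.assert_allclose(est.Pxy, pxy, rtol=1e-10)
        np.testing.assert_allclose(est.gain, np.abs(pxy / pxx), rtol=1e-10)
        np.testing.assert_allclose(est.msc, np.abs(pxy) ** 2 / (pxx * pyy), rtol=1e-10)

    def test_exact_linear_relation(self):
        x = np.random.default_rng(7).normal(size=1200)
        est = ab.estimate_transfer(x, 2.0 * x)
        assert np.allclose(est.gain[1:], 2.0, atol=1e-9)
        assert np.all(est.msc[1:] > 0.999)

    def test_independent_noise_coherence_shrinks_with_segments(self):
        # mean msc of independent white noise carries a ~1/K small-sample
        # bias for K averaged segments
        rng = np.random.default_rng(3)
        cfg = ab.SpectralConfig()
        for n, k in ((480, 7), (4800, 79)):
            m = []
            for _ in range(100):
                est = ab.estimate_transfer(rng.normal(size=n), rng.normal(size=n), cfg)
                m.append(np.mean(est.msc[1:]))
            mean = np.mean(m)
            assert 0.4 / k < mean < 2.5 / k

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ab.ValidationError):
            ab.estimate_transfer(np.zeros(200), np.zeros(199))

    def test_msc_bounded_and_gain_nonnegative(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=600) + np.sin(0.4 * np.arange(600))
        y = 0.5 * np.roll(x, 3) + rng.normal(size=600)
        est = ab.estimate_transfer(x, y)
        assert np.all((est.msc >= 0.0) & (est.msc <= 1.0))
        assert np.all(est.gain >= 0.0)

    def test_scale_covariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=600)
        y = np.roll(x, 2) + 0.3 * rng.normal(size=600)
        base = ab.estimate_transfer(x, y)
        cx = ab.estimate_transfer(3.0 * x, y)
        cy = ab.estimate_transfer(x, 3.0 * y)
        np.testing.assert_allclose(cx.gain, base.gain / 3.0, rtol=1e-9)
        np.testing.assert_allclose(cy.gain, base.gain * 3.0, rtol=1e-9)
        np.testing.assert_allclose(cx.msc, base.msc, rtol=1e-9)
        np.testing.assert_allclose(cy.msc, base.msc, rtol=1e-9)

    def test_output_noise_never_raises_mean_coherence(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=2400)
        y = 1.5 * x
        clean = np.mean(ab.estimate_transfer(x, y).msc)
        prev = clean
        for sd in (0.5, 2.0, 8.0):
            noisy = np.mean(ab.estimate_transfer(x, y + rng.normal(0, sd, 2400)).msc)
            assert noisy <= prev + 1e-6
            prev = noisy


class TestBRSIndex:
    def test_flat_gain_full_coherence(self):
        x = np.random.default_rng(1).normal(size=1200)
        idx = ab.brs_index(ab.estimate_transfer(x, 5.0 * x))
        assert idx.value == pytest.approx(5.0, abs=1e-6)
        assert idx.qualified

    def test_low_coherence_reported_but_unqualified(self):
        rng = np.random.default_rng(2)
        idx = ab.brs_index(ab.estimate_transfer(rng.normal(size=4800), rng.normal(size=4800)))
        assert not idx.qualified
        assert np.isfinite(idx.value)

    def test_lf_band_holds_three_bins_at_default_resolution(self):
        f = np.fft.rfftfreq(120, 0.25)
        bins = band_bins(f, (0.04, 0.15))
        np.testing.assert_allclose(f[bins], [2 / 30, 3 / 30, 4 / 30])

    def test_band_unresolved_raises(self):
        cfg = ab.SpectralConfig(segment_len=16, lf_band=(0.04, 0.12))
        x = np.random.default_rng(0).normal(size=64)
        est = ab.estimate_transfer(x, x, cfg)
        with pytest.raises(ab.WindowRejected, match="band_unresolved"):
            ab.brs_index(est, cfg)

    def test_simulated_gain_recovered(self):
        vals = []
        for seed in range(10):
            gt = ab.simulate_beats(ab.SimConfig(duration_s=300.0, seed=seed))
            idx, _ = ab.brs_from_beats(gt.beat_times, gt.sbp, gt.rr_ms)
            assert idx.qualified
            vals.append(idx.value)
        assert np.mean(vals) == pytest.approx(8.0, rel=0.1)


class TestHRVBandPower:
    def test_pure_lf_tone_parseval(self):
        t = np.arange(0, 600, 0.25)
        rr = 40.0 * np.sin(2 * np.pi * 0.1 * t)
        lf = ab.hrv_band_power(rr, (0.04, 0.15))
        hf = ab.hrv_band_power(rr, (0.15, 0.40))
        assert lf == pytest.approx(40.0**2 / 2, rel=0.02)
        assert hf < 0.01 * lf

    def test_hf_tone_lands_in_hf_band(self):
        t = np.arange(0, 600, 0.25)
        rr = 25.0 * np.sin(2 * np.pi * 0.25 * t)
        assert ab.hrv_band_power(rr, (0.15, 0.40)) == pytest.approx(25.0**2 / 2, rel=0.02)
        assert ab.hrv_band_power(rr, (0.04, 0.15)) < 0.01 * 25.0**2 / 2

    def test_white_noise_band_ratio_tracks_bandwidth(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(100):
            rr = rng.normal(size=2400)
            ratios.append(
                ab.hrv_band_power(rr, (0.04, 0.15)) / ab.hrv_band_power(rr, (0.15, 0.40))
            )
        # bandwidth ratio 0.11/0.25, with discrete-bin granularity at df=1/30
        assert np.mean(ratios) == pytest.approx(0.11 / 0.25, rel=0.25)
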