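"""Multitaper power, baseline normalization, coherence, spectrograms, bands."""

import numpy as np
import pytest

import laminargc as lg
from laminargc.spectral import (
    DEFAULT_BANDS, TaperSpec, band_average, coherence, find_peak_frequency,
    multitaper_power, normalize_to_baseline, sliding_spectrogram,
)

FS = 1017.375


class TestTaperSpec:
    def test_leakage_bound_enforced(self):
        with pytest.raises(ValueError, match="2\\*TW-1"):
            TaperSpec(K=4, TW=2.0)

    def test_frequency_resolution_and_half_bandwidth(self, taper):
        freqs = np.fft.rfftfreq(taper.N, 1.0 / FS)
        assert freqs[1] == pytest.approx(FS / 512)           # ~2 Hz
        assert taper.half_bandwidth_hz(FS) == pytest.approx(3.974, abs=0.01)


class TestPower:
    def test_zero_epochs_zero_power(self, taper):
        res = multitaper_power(np.zeros((3, 2, 512)), FS, taper)
        assert np.allclose(res.values, 0.0)

    def test_white_noise_parseval_against_periodogram(self, taper, rng):
        """Integrated multitaper PSD of unit white noise equals the variance,
        matching a plain periodogram oracle; spectrum is flat."""
        x = rng.standard_normal((200, 1, 512))
        res = multitaper_power(x, FS, taper)
        df = res.freqs[1]
        total = res.values[0].sum() * df
        var = x.var()
        assert total == pytest.approx(var, rel=0.05)
        # independent oracle: raw periodogram (boxcar, no taper)
        xd = x - x.mean(axis=-1, keepdims=True)
        pgram = (np.abs(np.fft.rfft(xd, axis=-1)) ** 2).mean(axis=(0, 1)) / (FS * 512)
        pgram[1:] *= 2; pgram[-1] /= 2
        assert total == pytest.approx(pgram.sum() * df, rel=0.05)
        banded = band_average(res.values[0], res.freqs)
        flat = np.array(list(banded.values()))
        assert flat.std() / flat.mean() < 0.1

    def test_mean_offset_invariance(self, taper, rng):
        x = rng.standard_normal((10, 2, 512))
        shifted = x + 17.0
        a = multitaper_power(x, FS, taper).values
        b = multitaper_power(shifted, FS, taper).values
        assert np.allclose(a, b)

    def test_wrong_epoch_length_rejected(self, taper):
        with pytest.raises(ValueError, match="taper.N"):
            multitaper_power(np.zeros((2, 1, 100)), FS, taper)


class TestBaselineNormalization:
    def test_power_equal_to_baseline_gives_zero(self, taper, rng):
        x = rng.standard_normal((40, 2, 512))
        per_trial = multitaper_power(x, FS, taper, trial_average=False).values
        res = multitaper_power(x, FS, taper)
        z = normalize_to_baseline(res, per_trial)
        assert np.abs(z.values).max() < 1e-9
        assert z.normalization == "baseline_z"

    def test_z_formula(self):
        res = lg.SpectralResult(freqs=np.arange(3.0), values=np.full((1, 3), 5.0))
        base = np.stack([np.full((1, 3), 2.0), np.full((1, 3), 4.0)])
        z = normalize_to_baseline(res, base)     # mean 3, sd sqrt(2)
        assert np.allclose(z.values, 2.0 / np.sqrt(2.0))

    def test_zero_baseline_sd_names_frequency(self):
        res = lg.SpectralResult(freqs=np.arange(3.0), values=np.ones((1, 3)))
        base = np.ones((5, 1, 3))
        with pytest.raises(ZeroDivisionError, match="frequencies"):
            normalize_to_baseline(res, base)

    def test_shorter_baseline_grid_interpolated(self, taper, rng):
        """Baseline epochs of 234 samples have a coarser grid; their spectra
        are interpolated onto the 512-sample analysis grid."""
        x = rng.standard_normal((30, 2, 512))
        base = rng.standard_normal((30, 2, 234))
        tb = TaperSpec(N=234)
        base_power = multitaper_power(base, FS, tb, trial_average=False).values
        base_freqs = np.fft.rfftfreq(234, 1.0 / FS)
        res = multitaper_power(x, FS, taper)
        z = normalize_to_baseline(res, base_power, base_freqs)
        assert z.values.shape == res.values.shape
        assert np.isfinite(z.values).all()


class TestCoherence:
    def test_identical_signals_coherence_one(self, taper, rng):
        x = rng.standard_normal((5, 1, 512))
        x = np.concatenate([x, x], axis=1)
        res = coherence(x, [(0, 1)], FS, taper)
        assert np.allclose(res.values, 1.0)

    def test_independent_noise_bias_matches_analytic(self, taper, rng):
        """E[C] for independent Gaussians is ~1/(K n) under joint pooling."""
        n_trials = 500
        x = rng.standard_normal((n_trials, 2, 512))
        res = coherence(x, [(0, 1)], FS, taper)
        expected = 1.0 / (taper.K * n_trials)
        assert res.values.mean() == pytest.approx(expected, rel=0.3)

    def test_shared_oscillator_peaks_at_its_frequency(self, taper):
        cfg = lg.GeneratorConfig(
            n_trials_per_condition=40, n_channels=2, probes=("V1",),
            n_samples=512, evoked=None, epoch_alignment="pre_dimming",
            oscillators=[lg.Oscillator(f0=40.0, bandwidth=8.0, probe="V1",
                                       amplitude=1.0)],
            seed=5)
        s = lg.generate_session(cfg)
        res = coherence(s.lfp, [(0, 1)], s.fs, taper)
        pk = find_peak_frequency(res.values[0], res.freqs, (10.0, 100.0))
        assert abs(pk.frequency_hz - 40.0) <= 2 * FS / 512

    def test_symmetry_exact(self, taper, rng):
        x = rng.standard_normal((8, 2, 512))
        res = coherence(x, [(0, 1), (1, 0)], FS, taper)
        assert np.array_equal(res.values[0], res.values[1])

    def test_values_in_unit_interval(self, taper, rng):
        x = rng.standard_normal((4, 3, 512))
        res = coherence(x, [(0, 1), (0, 2)], FS, taper)
        assert (res.values >= 0).all() and (res.values <= 1).all()

    def test_single_taper_single_trial_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            coherence(np.zeros((1, 2, 64)), [(0, 1)], FS, TaperSpec(K=1, TW=1, N=64))


class TestSlidingSpectrogram:
    def test_window_count_over_double_span(self, taper, rng):
        x = rng.standard_normal((2, 1, 1024))     # ~1006.5 ms at fs
        tf = sliding_spectrogram(x, FS, taper, step_ms=20.0)
        assert tf.values.shape[0] == 26
        assert tf.times_ms[-1] == pytest.approx(-503.25 / 2, abs=1.0)

    def test_step_equal_to_remainder_gives_two_windows(self, rng):
        t = TaperSpec(N=128)
        x = rng.standard_normal((2, 1, 192))
        step_ms = 64 / FS * 1000.0
        tf = sliding_spectrogram(x, FS, t, step_ms=step_ms)
        assert tf.values.shape[0] == 2

    def test_span_shorter_than_window_rejected(self, taper):
        with pytest.raises(ValueError, match="shorter than window"):
            sliding_spectrogram(np.zeros((1, 1, 256)), FS, taper)

    def test_stationary_input_gives_stable_window_spectra(self, rng):
        t = TaperSpec(N=128)
        x = rng.standard_normal((50, 1, 512))
        tf = sliding_spectrogram(x, FS, t, step_ms=50.0)
        per_window = tf.values[:, 0, 1:-1].mean(axis=1)
        assert per_window.std() / per_window.mean() < 0.1


class TestBands:
    def test_constant_spectrum_gives_constant_band_means(self):
        freqs = np.fft.rfftfreq(512, 1.0 / FS)
        out = band_average(np.full(freqs.size, 3.0), freqs)
        assert all(v == pytest.approx(3.0) for v in out.values())

    def test_single_frequency_lands_in_alpha_only(self):
        freqs = np.fft.rfftfreq(512, 1.0 / FS)
        v = np.zeros(freqs.size)
        v[np.argmin(np.abs(freqs - 10.0))] = 1.0
        out = band_average(v, freqs)
        assert out["alpha"] > 0
        assert all(out[b] == 0 for b in out if b != "alpha")

    def test_edge_frequency_counts_in_upper_band(self):
        freqs = np.arange(0.0, 100.0, 1.0)    # contains exactly 8 Hz
        v = np.zeros(freqs.size)
        v[8] = 1.0
        out = band_average(v, freqs)
        assert out["alpha"] > 0 and out["theta"] == 0

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            band_average(np.ones(3), np.array([0.0, 100.0, 200.0]),
                         {"theta": (4.0, 8.0)})


class TestPeakFrequency:
    def test_monotone_spectrum_flags_no_interior_peak(self):
        freqs = np.linspace(0, 100, 101)
        pk = find_peak_frequency(freqs.copy(), freqs, (25.0, 50.0))
        assert not pk.interior

    def test_tie_resolves_to_lower_frequency(self):
        freqs = np.linspace(0, 100, 101)
        v = np.zeros(101)
        v[30] = v[40] = 1.0
        pk = find_peak_frequency(v, freqs, (25.0, 50.0), smooth=False)
        assert pk.frequency_hz == 30.0

    def test_flat_spectrum_flagged(self):
        freqs = np.linspace(0, 100, 101)
        pk = find_peak_frequency(np.ones(101), freqs, (25.0, 50.0))
        assert pk.flat
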