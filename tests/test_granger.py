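"""VAR fitting and conditional spectral Granger causality."""

import warnings

import numpy as np
import pytest

from laminargc.granger import (
    conditional_spectral_gc, fit_var, pairwise_cgc, shuffle_null_threshold,
    time_domain_cgc,
)
from laminargc.preprocess import bipolar_rereference
from laminargc.validation import analytic_var1_gc, simulate_var1

FS = 1017.375


def simulate_var(coefs, n_trials, n_samples, seed, burn=100):
    coefs = np.asarray(coefs, dtype=float)
    p, d, _ = coefs.shape
    rng = np.random.default_rng(seed)
    x = np.zeros((n_trials, d, n_samples + burn))
    for t in range(p, n_samples + burn):
        acc = rng.standard_normal((n_trials, d))
        for k in range(p):
            acc += x[:, :, t - k - 1] @ coefs[k].T
        x[:, :, t] = acc
    return x[:, :, burn:]


class TestFitVar:
    def test_known_var2_coefficients_recovered(self):
        coefs = np.array([[[0.4, 0.15], [0.0, 0.3]],
                          [[-0.25, 0.0], [0.1, -0.2]]])
        x = simulate_var(coefs, 200, 512, seed=0)
        m = fit_var(x, order=2)
        assert np.abs(m.coefs - coefs).max() < 0.05
        assert np.abs(m.sigma - np.eye(2)).max() < 0.05
        assert m.spectral_radius < 1

    def test_white_noise_selects_small_order(self, rng):
        x = rng.standard_normal((50, 2, 256))
        m = fit_var(x, p_max=6)
        assert m.order <= 2
        sample_cov = np.cov(x.reshape(-1, 2).T)  # ~identity
        assert np.abs(m.sigma - sample_cov).max() < 0.05

    def test_duplicated_channel_raises_singular(self, rng):
        x = rng.standard_normal((20, 1, 256))
        dup = np.concatenate([x, x], axis=1)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_var(dup, order=2)

    def test_guard_ratio_enforced(self, rng):
        x = rng.standard_normal((1, 4, 64))
        with pytest.raises(ValueError, match="guard ratio"):
            fit_var(x, order=10)


class TestConditionalGC:
    def test_independent_channels_have_tiny_cgc(self, rng):
        x = rng.standard_normal((80, 3, 256))
        res = conditional_spectral_gc(x, 0, 1, [2], fs=FS, order=2)
        assert res.cgc.mean() < 0.01

    def test_nonnegative_everywhere(self, rng):
        x = rng.standard_normal((40, 2, 256))
        res = conditional_spectral_gc(x, 0, 1, fs=FS, order=3)
        assert (res.cgc >= 0).all()

    def test_geweke_integral_identity_against_analytic_oracle(self):
        """Frequency-averaged spectral cGC equals the closed-form
        time-domain GC of the generating VAR(1) (reduced-size replicate;
        the full-size 2% check lives in the acceptance suite)."""
        a, b, c = 0.5, 0.7, 0.4
        x = simulate_var1(a, b, c, n_trials=150, n_samples=384, seed=3)
        freqs = np.linspace(0.0, FS / 2, 385)
        res = conditional_spectral_gc(x, 0, 1, fs=FS, freqs=freqs, order=1)
        favg = np.trapezoid(res.cgc[0], freqs) / (FS / 2)
        assert favg == pytest.approx(analytic_var1_gc(a, b, c), rel=0.05)

    def test_spectral_average_matches_fitted_time_domain(self):
        x = simulate_var1(0.5, 0.7, 0.4, n_trials=100, n_samples=256, seed=9)
        freqs = np.linspace(0.0, FS / 2, 257)
        res = conditional_spectral_gc(x, 0, 1, fs=FS, freqs=freqs, order=1)
        favg = np.trapezoid(res.cgc[0], freqs) / (FS / 2)
        full = fit_var(x, order=1)
        reduced = fit_var(x[:, [1]], order=12)
        assert favg == pytest.approx(time_domain_cgc(full, reduced), rel=0.05)

    def test_chain_conditioning_removes_indirect_path(self, rng):
        x = rng.standard_normal((80, 3, 256))
        for t in range(1, 256):
            x[:, 1, t] += 0.6 * x[:, 0, t - 1]   # X -> Z
            x[:, 2, t] += 0.6 * x[:, 1, t - 1]   # Z -> Y
        pairwise = conditional_spectral_gc(x, 0, 2, fs=FS, order=3)
        cond = conditional_spectral_gc(x, 0, 2, [1], fs=FS, order=3)
        assert pairwise.cgc.mean() > 10 * cond.cgc.mean()

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((40, 3, 256))
        for t in range(1, 256):
            x[:, 1, t] += 0.4 * x[:, 0, t - 1]
        a = conditional_spectral_gc(x, 0, 1, [2], fs=FS, order=2)
        b = conditional_spectral_gc(5.0 * x, 0, 1, [2], fs=FS, order=2)
        assert np.allclose(a.cgc, b.cgc, atol=1e-10)

    def test_overlapping_sets_rejected(self, rng):
        x = rng.standard_normal((10, 3, 128))
        with pytest.raises(ValueError, match="disjoint"):
            conditional_spectral_gc(x, 0, 0, fs=FS, order=1)
        with pytest.raises(ValueError, match="disjoint"):
            conditional_spectral_gc(x, 0, 1, [0], fs=FS, order=1)


class TestShuffleNull:
    def test_threshold_nonnegative_and_detects_coupling(self, rng):
        x = rng.standard_normal((60, 2, 256))
        for t in range(2, 256):
            x[:, 1, t] += 0.5 * x[:, 0, t - 2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr, _ = shuffle_null_threshold(x, 0, 1, fs=FS, order=3,
                                            n_shuffles=40, seed=0)
            res = conditional_spectral_gc(x, 0, 1, fs=FS, order=3)
        assert (thr >= 0).all()
        assert res.cgc.mean() > thr.mean()

    def test_shuffle_count_and_trial_guards(self, rng):
        x = rng.standard_normal((2, 2, 128))
        with pytest.raises(ValueError, match="3 trials"):
            shuffle_null_threshold(x, 0, 1, fs=FS, n_shuffles=30)
        x = rng.standard_normal((10, 2, 128))
        with pytest.raises(ValueError, match=">= 20"):
            shuffle_null_threshold(x, 0, 1, fs=FS, n_shuffles=5)


class TestPairwise:
    def test_all_ordered_pairs_present_within_probes(self, coupled_session):
        bip = bipolar_rereference(coupled_session)
        res = pairwise_cgc(bip, scope="within", order=3, conditioning_cap=1)
        # 3 derivations per probe -> 3*2 ordered pairs per probe
        assert len(res.pairs) == 12
        assert all((t, s) in res.pairs for (s, t) in res.pairs)
        assert (res.cgc >= 0).all()
        for (s, t), z in zip(res.pairs, res.conditioning):
            assert s not in z and t not in z
            assert len(z) <= 1

    def test_between_probe_scope_pair_count(self, coupled_session):
        bip = bipolar_rereference(coupled_session)
        res = pairwise_cgc(bip, scope="between", order=3, conditioning_cap=2)
        assert len(res.pairs) == 18     # 3x3 cross pairs, both directions
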