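"""Multitaper spectral power, coherence, and time-frequency maps.

Power and coherence are estimated with K Slepian (DPSS) tapers of
time-bandwidth product TW on N-sample epochs (defaults K=3, TW=2, N=512),
giving a half-bandwidth W = TW/T of about 4 Hz at fs = 1017.375 Hz and a
frequency resolution of fs/N ≈ 2 Hz.  Cross- and auto-spectra are pooled
over tapers and trials jointly before forming the coherence ratio
|S_ij|^2 / (S_i S_j), which lies in [0, 1].

Power can be z-scored against per-trial baseline spectra (subtract the
trial-averaged baseline power, divide by its SD across trials).  Band
summaries use the conventional intervals theta [4,8), alpha [8,13),
beta [13,25), low gamma [25,50), high gamma [50,80] Hz, lower edge
inclusive, upper exclusive (last band upper-inclusive), DC and Nyquist
bins excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import interp1d
from scipy.ndimage import uniform_filter1d
from scipy.signal.windows import dpss

DEFAULT_BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 25.0),
    "low_gamma": (25.0, 50.0),
    "high_gamma": (50.0, 80.0),
}


@dataclass
class TaperSpec:
    """Slepian taper family: K tapers, time-bandwidth product TW, N samples."""

    K: int = 3
    TW: float = 2.0
    N: int = 512

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.K > 2 * self.TW - 1:
            raise ValueError(
                f"K={self.K} tapers exceed the leakage bound 2*TW-1={2 * self.TW - 1:g}"
            )

    def tapers(self, n: Optional[int] = None) -> np.ndarray:
        return dpss(n or self.N, self.TW, self.K)

    def half_bandwidth_hz(self, fs: float, n: Optional[int] = None) -> float:
        return self.TW * fs / (n or self.N)


@dataclass
class SpectralResult:
    freqs: np.ndarray               # Hz, 0 .. fs/2 in steps of fs/N
    values: np.ndarray              # (n_units, n_freqs)
    kind: str = "power"             # "power" | "coherence"
    normalization: str = "raw"      # "raw" | "baseline_z"
    units: Optional[list] = None    # channel indices or (i, j) pairs


@dataclass
class TimeFreqMap:
    times_ms: np.ndarray            # window centers, event-relative
    freqs: np.ndarray
    values: np.ndarray              # (n_windows, n_units, n_freqs)
    window_samples: int
    step_ms: float

    def __post_init__(self) -> None:
        steps = np.diff(self.times_ms)
        if steps.size and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("window times must increase with a constant step")


def _tapered_fft(epochs: np.ndarray, taper: TaperSpec) -> np.ndarray:
    """Demean per trial/channel, taper, and rFFT: (trial, ch, taper, freq)."""
    x = np.asarray(epochs, dtype=float)
    if x.ndim == 2:
        x = x[np.newaxis]
    n = x.shape[-1]
    x = x - x.mean(axis=-1, keepdims=True)
    tap = taper.tapers(n)
    return np.fft.rfft(x[:, :, None, :] * tap[None, None, :, :], axis=-1)


def multitaper_power(
    epochs: np.ndarray,
    fs: float,
    taper: Optional[TaperSpec] = None,
    trial_average: bool = True,
) -> SpectralResult:
    """One-sided multitaper power spectral density per channel.

    ``epochs`` is (n_trials, n_channels, N) with N = taper.N.  Per-trial
    means are removed, power is averaged over tapers (and trials unless
    ``trial_average`` is False, in which case values keep a leading trial
    axis).  Scaled so that the integral over frequency equals the signal
    variance (Parseval).
    """
    taper = taper or TaperSpec()
    x = np.asarray(epochs, dtype=float)
    if x.ndim == 2:
        x = x[np.newaxis]
    if x.shape[-1] != taper.N:
        raise ValueError(f"epoch length {x.shape[-1]} != taper.N {taper.N}")
    xk = _tapered_fft(x, taper)
    power = (np.abs(xk) ** 2).mean(axis=2) / fs
    power[..., 1:] *= 2.0
    if x.shape[-1] % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    if trial_average:
        power = power.mean(axis=0)
    return SpectralResult(freqs=freqs, values=power, kind="power",
                          units=list(range(x.shape[1])))


def normalize_to_baseline(
    power: SpectralResult,
    baseline_per_trial: np.ndarray,
    baseline_freqs: Optional[np.ndarray] = None,
) -> SpectralResult:
    """Baseline z-normalization of a power spectrum.

    z(f) = (S(f) - mean_trials S_base(f)) / SD_trials S_base(f), per
    channel and frequency.  ``baseline_per_trial`` is
    (n_trials, n_channels, n_base_freqs); if its frequency grid differs
    from the analysis grid (baseline epochs are shorter), it is linearly
    interpolated onto ``power.freqs``.
    """
    base = np.asarray(baseline_per_trial, dtype=float)
    if baseline_freqs is not None and (
        base.shape[-1] != power.freqs.size
        or not np.allclose(baseline_freqs, power.freqs)
    ):
        base = interp1d(
            baseline_freqs, base, axis=-1, bounds_error=False,
            fill_value="extrapolate", assume_sorted=True,
        )(power.freqs)
    mean = base.mean(axis=0)
    sd = base.std(axis=0, ddof=1)
    bad = np.flatnonzero((sd == 0).any(axis=0))
    if bad.size:
        raise ZeroDivisionError(
            f"zero baseline SD at frequencies {power.freqs[bad][:5]} Hz"
        )
    return SpectralResult(
        freqs=power.freqs, values=(power.values - mean) / sd,
        kind=power.kind, normalization="baseline_z", units=power.units,
    )


def coherence(
    epochs: np.ndarray,
    pairs: list,
    fs: float,
    taper: Optional[TaperSpec] = None,
) -> SpectralResult:
    """Magnitude-squared multitaper coherence for the given channel pairs.

    Cross- and auto-spectra are averaged jointly over all taper-trial
    products before forming C_ij = |S_ij|^2 / (S_i S_j).  At least two
    taper-trial samples are required (a single product is identically 1).
    C is symmetric in (i, j) and lies in [0, 1]; its small-sample bias for
    independent signals is about 1/(K * n_trials).
    """
    taper = taper or TaperSpec()
    x = np.asarray(epochs, dtype=float)
    if x.ndim == 2:
        x = x[np.newaxis]
    if x.shape[0] * taper.K < 2:
        raise ValueError(
            "coherence needs >= 2 taper-trial samples; a single taper of a "
            "single trial is degenerate (identically 1)"
        )
    xk = _tapered_fft(x, taper)          # (trial, ch, taper, freq)
    auto = (np.abs(xk) ** 2).mean(axis=(0, 2))
    vals = np.empty((len(pairs), xk.shape[-1]))
    for k, (i, j) in enumerate(pairs):
        # canonical order makes C_ij and C_ji bitwise identical
        a, b = (i, j) if i <= j else (j, i)
        sij = (xk[:, a] * np.conj(xk[:, b])).mean(axis=(0, 1))
        vals[k] = np.abs(sij) ** 2 / (auto[a] * auto[b])
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    return SpectralResult(freqs=freqs, values=np.clip(vals, 0.0, 1.0),
                          kind="coherence", units=list(pairs))


def sliding_spectrogram(
    traces: np.ndarray,
    fs: float,
    taper: Optional[TaperSpec] = None,
    step_ms: float = 20.0,
    pairs: Optional[list] = None,
) -> TimeFreqMap:
    """Sliding-window multitaper power (or coherence) map.

    ``traces`` is (n_trials, n_channels, n_total); windows of taper.N
    samples step every ``step_ms`` and are right-aligned so the last
    window ends exactly at the final sample (the alignment event).  Window
    times are the centers in ms relative to that event (negative).
    A 1006.5 ms span with 503.25 ms windows and 20 ms steps gives 26
    windows.
    """
    taper = taper or TaperSpec()
    x = np.asarray(traces, dtype=float)
    if x.ndim == 2:
        x = x[np.newaxis]
    total = x.shape[-1]
    if total < taper.N:
        raise ValueError(f"span of {total} samples shorter than window {taper.N}")
    step = int(round(step_ms / 1000.0 * fs))
    n_win = (total - taper.N) // step + 1
    values, times = [], []
    for k in range(n_win):
        end = total - (n_win - 1 - k) * step
        seg = x[:, :, end - taper.N:end]
        if pairs is None:
            res = multitaper_power(seg, fs, taper)
        else:
            res = coherence(seg, pairs, fs, taper)
        values.append(res.values)
        times.append(1000.0 * (end - taper.N / 2.0 - total) / fs)
    return TimeFreqMap(
        times_ms=np.asarray(times), freqs=res.freqs,
        values=np.stack(values), window_samples=taper.N, step_ms=step_ms,
    )


def _band_mask(freqs: np.ndarray, lo: float, hi: float, last: bool,
               fs_nyquist: float) -> np.ndarray:
    mask = (freqs >= lo) & ((freqs <= hi) if last else (freqs < hi))
    mask &= (freqs > 0) & (freqs < fs_nyquist)   # drop DC and Nyquist
    return mask


def band_average(
    values: np.ndarray,
    freqs: np.ndarray,
    bands: Optional[dict] = None,
) -> dict:
    """Arithmetic mean of spectral values over each named band.

    ``values`` may have any shape with frequency as the last axis.  Band
    edges are lower-inclusive / upper-exclusive except the last band,
    which includes its upper edge; DC and Nyquist bins never count.
    """
    bands = bands or DEFAULT_BANDS
    names = list(bands)
    out = {}
    for name in names:
        lo, hi = bands[name]
        mask = _band_mask(freqs, lo, hi, name == names[-1], freqs[-1])
        if not mask.any():
            raise ValueError(f"band {name} [{lo}, {hi}] empty on the frequency grid")
        out[name] = np.asarray(values)[..., mask].mean(axis=-1)
    return out


@dataclass
class PeakResult:
    frequency_hz: float
    interior: bool       # False: maximum sits at a band edge (no interior peak)
    flat: bool = False   # spectrum flat within tolerance: no peak at all


def find_peak_frequency(
    values: np.ndarray,
    freqs: np.ndarray,
    band: tuple,
    smooth: bool = True,
    flat_tol: float = 1e-12,
) -> PeakResult:
    """Frequency of the spectral maximum within a band.

    An optional 3-bin moving average (default on) suppresses single-bin
    jitter.  Ties resolve to the lower frequency; a flat spectrum sets the
    ``flat`` flag, and a maximum at a band edge clears ``interior``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be a single spectrum")
    if smooth:
        v = uniform_filter1d(v, size=3, mode="nearest")
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("band empty on frequency grid")
    vb, fb = v[mask], freqs[mask]
    if vb.max() - vb.min() <= flat_tol:
        return PeakResult(frequency_hz=float(fb[0]), interior=False, flat=True)
    k = int(np.argmax(vb))
    return PeakResult(frequency_hz=float(fb[k]), interior=0 < k < vb.size - 1)
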