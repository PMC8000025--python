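"""Synthetic two-probe laminar recording generator with known ground truth.

Sessions emulate the structure of a laminar attention experiment: two
16-contact probes (areas V1 and V4, 150 µm spacing), trials split across
three attention conditions (attend-RF, OUT1, OUT2), band-limited
oscillations whose gain and center frequency may depend on condition,
directed lagged couplings between channels (so the latent system is
exactly a stable vector autoregression), 1/f background noise, and a
stimulus-evoked granular current sink pushed through the disc forward
model so inverse-CSD alignment can recover it.

Every downstream stage of the pipeline is testable against the embedded
``ground_truth`` configuration: which channels are coupled, in which
direction and at what lag, which condition carries more gamma power, and
where the granular sink sits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .laminar import conduction_matrix
from .session import CONDITIONS, SessionRecording


def forward_potentials(
    csd_amplitudes: np.ndarray,
    spacing_um: float = 150.0,
    r_um: float = 500.0,
    sigma: float = 0.4,
    interpolation: str = "spline",
) -> np.ndarray:
    """Potentials Phi = F C generated by a laminar CSD profile.

    ``csd_amplitudes`` holds the CSD node values on an evenly spaced depth
    grid (``spacing_um`` apart); columns may carry time.  F is the uniform
    disc conduction matrix (radius ``r_um``, conductivity ``sigma``) built
    under cubic-spline depth interpolation by default — the exact matrix
    the inverse-CSD stage inverts.  ``interpolation="step"`` instead treats
    each node as an independent disc slab of one spacing thickness, whose
    potential is the closed-form kernel itself.  Phi is proportional to
    1/sigma.
    """
    c = np.asarray(csd_amplitudes, dtype=float)
    if not np.isfinite(c).all():
        raise ValueError("CSD amplitudes must be finite")
    depths = np.arange(c.shape[0], dtype=float) * spacing_um
    fmat = conduction_matrix(depths, r_um, sigma, interpolation=interpolation)
    return fmat @ c


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _cond(d: Optional[dict], condition: str, default: float) -> float:
    if not d:
        return default
    return float(d.get(condition, default))


@dataclass
class Oscillator:
    """Band-limited latent oscillator living on one probe.

    A fresh white-noise sequence per trial is band-pass filtered (two
    second-order Butterworth sections, i.e. a 4-pole filter) around the
    per-condition center frequency and mixed onto the probe's contacts
    through ``depth_profile``.
    """

    f0: float                       # center frequency, Hz
    bandwidth: float = 10.0         # full passband width, Hz
    probe: str = "V1"
    amplitude: float = 1.0
    depth_profile: Optional[Sequence[float]] = None   # per-contact weights
    gain: Optional[dict] = None     # condition -> amplitude gain (default 1)
    df: Optional[dict] = None       # condition -> center-frequency offset Hz


@dataclass
class Coupling:
    """Directed lagged linear coupling between channel sets."""

    source_probe: str
    source_channels: Sequence[int]  # within-probe contact indices
    target_probe: str
    target_channels: Sequence[int]
    lag: int = 2                    # samples
    gain: float = 0.3
    condition_gain: Optional[dict] = None   # multiplicative, default 1

    def label(self) -> str:
        return (
            f"{self.source_probe}{list(self.source_channels)}->"
            f"{self.target_probe}{list(self.target_channels)} lag={self.lag}"
        )


@dataclass
class Evoked:
    """Stimulus-evoked granular sink/source CSD profile.

    The per-depth CSD (a sink of unit depth-integral at ``sink_channel``
    flanked by balancing return sources) is pushed through
    :func:`forward_potentials` and scaled so the peak evoked potential is
    ``amplitude_uv``; the temporal envelope is a Gaussian bump at
    ``latency_ms`` with SD ``width_ms``.
    """

    sink_channel: int = 8           # within-probe contact index of the sink
    amplitude_uv: float = 30.0
    latency_ms: float = 40.0
    width_ms: float = 10.0
    return_spread: int = 2          # contacts between sink and return sources


@dataclass
class NoiseSpec:
    exponent: float = 1.0           # 1/f^exponent power shaping
    sd: float = 1.0                 # µV per channel


@dataclass
class GeneratorConfig:
    n_trials_per_condition: int = 30
    n_channels: int = 16            # per probe
    probes: Sequence[str] = ("V1", "V4")
    spacing_um: float = 150.0
    fs: float = 1017.375
    n_samples: int = 512
    n_baseline_samples: int = 234   # (-200, +30) ms around stimulus onset
    oscillators: Sequence[Oscillator] = field(default_factory=list)
    couplings: Sequence[Coupling] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    evoked: Optional[Evoked] = field(default_factory=Evoked)
    disc_radius_um: float = 500.0
    sigma_s_per_m: float = 0.4
    epoch_alignment: str = "stimulus_onset"
    with_mua: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0 or self.n_samples <= 0:
            raise ValueError("fs and n_samples must be positive")
        if self.n_trials_per_condition <= 0:
            raise ValueError("need at least one trial per condition")
        for osc in self.oscillators:
            vals = [osc.amplitude] + list((osc.gain or {}).values())
            if not np.isfinite(vals).all():
                raise ValueError("oscillator gains must be finite")
            if not 0 < osc.f0 < self.fs / 2:
                raise ValueError("oscillator frequency outside (0, fs/2)")
        for c in self.couplings:
            vals = [c.gain] + list((c.condition_gain or {}).values())
            if not np.isfinite(vals).all():
                raise ValueError(f"non-finite gain in coupling {c.label()}")
            if c.lag < 1:
                raise ValueError("coupling lag must be >= 1 sample")
        if self.evoked is not None:
            if not 0 <= self.evoked.latency_ms <= 1000.0 * self.n_samples / self.fs:
                raise ValueError("evoked sink latency outside the epoch")
            if not 0 <= self.evoked.sink_channel < self.n_channels:
                raise ValueError("evoked sink channel outside the probe")

    # -- (de)serialization for YAML configs and the HDF5 container ---------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["probes"] = list(self.probes)
        for osc in d["oscillators"]:
            if osc["depth_profile"] is not None:
                osc["depth_profile"] = list(np.asarray(osc["depth_profile"], float))
        for c in d["couplings"]:
            c["source_channels"] = [int(i) for i in c["source_channels"]]
            c["target_channels"] = [int(i) for i in c["target_channels"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["oscillators"] = [Oscillator(**o) for o in d.get("oscillators", [])]
        d["couplings"] = [Coupling(**c) for c in d.get("couplings", [])]
        if isinstance(d.get("noise"), dict):
            d["noise"] = NoiseSpec(**d["noise"])
        if isinstance(d.get("evoked"), dict):
            d["evoked"] = Evoked(**d["evoked"])
        d["probes"] = tuple(d.get("probes", ("V1", "V4")))
        return cls(**d)


class UnstableCouplingError(ValueError):
    """Coupling specification implies an unstable lag-transition operator."""


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _coupling_matrices(config: GeneratorConfig, condition: str) -> np.ndarray:
    """Lag-indexed transition matrices A[k-1] for one condition."""
    n_total = config.n_channels * len(config.probes)
    probe_offset = {p: i * config.n_channels for i, p in enumerate(config.probes)}
    max_lag = max((c.lag for c in config.couplings), default=1)
    a = np.zeros((max_lag, n_total, n_total))
    for c in config.couplings:
        g = c.gain * _cond(c.condition_gain, condition, 1.0)
        for s in c.source_channels:
            for t in c.target_channels:
                a[c.lag - 1,
                  probe_offset[c.target_probe] + t,
                  probe_offset[c.source_probe] + s] += g
    return a


def _check_stability(config: GeneratorConfig) -> None:
    for condition in CONDITIONS:
        a = _coupling_matrices(config, condition)
        p, d, _ = a.shape
        companion = np.zeros((p * d, p * d))
        companion[:d] = a.transpose(1, 0, 2).reshape(d, p * d)
        if p > 1:
            companion[d:, :-d] = np.eye((p - 1) * d)
        radius = np.abs(np.linalg.eigvals(companion)).max()
        if radius >= 1.0:
            worst = max(
                config.couplings,
                key=lambda c: abs(c.gain * _cond(c.condition_gain, condition, 1.0)),
            )
            raise UnstableCouplingError(
                f"coupling specification unstable in condition {condition} "
                f"(spectral radius {radius:.3f} >= 1); strongest coupling: "
                f"{worst.label()}"
            )


def _one_over_f(rng: np.random.Generator, n_ch: int, n: int,
                exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise."""
    white = rng.standard_normal((n_ch, n))
    if exponent == 0:
        return sd * white
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shape, n=n, axis=-1)
    rms = shaped.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return sd * shaped / rms


def _bandpass_sos(f0: float, bw: float, fs: float):
    lo = max(f0 - bw / 2.0, 0.1)
    hi = min(f0 + bw / 2.0, fs / 2.0 * 0.99)
    return signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _evoked_potentials(config: GeneratorConfig) -> np.ndarray:
    """Per-contact evoked waveform (n_channels, n_samples) for one probe."""
    ev = config.evoked
    csd = np.zeros(config.n_channels)
    csd[ev.sink_channel] = -1.0
    for off in (-ev.return_spread, ev.return_spread):
        j = ev.sink_channel + off
        if 0 <= j < config.n_channels:
            csd[j] += 0.5
    phi = forward_potentials(
        csd, config.spacing_um, config.disc_radius_um, config.sigma_s_per_m
    )
    phi = phi / np.abs(phi).max() * ev.amplitude_uv
    t_ms = np.arange(config.n_samples) / config.fs * 1000.0
    wave = np.exp(-0.5 * ((t_ms - ev.latency_ms) / ev.width_ms) ** 2)
    return phi[:, None] * wave[None, :]


def _mua_envelope(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """MUA-envelope epoch with the shortest response latency at the sink."""
    ev = config.evoked
    n_total = config.n_channels * len(config.probes)
    t_ms = np.arange(config.n_samples) / config.fs * 1000.0
    env = 0.05 * np.abs(rng.standard_normal((n_total, config.n_samples)))
    for ip in range(len(config.probes)):
        for ch in range(config.n_channels):
            dist = abs(ch - ev.sink_channel)
            lat = ev.latency_ms + 1.5 * dist
            amp = max(0.2, 1.0 - 0.1 * dist)
            env[ip * config.n_channels + ch] += amp / (
                1.0 + np.exp(-(t_ms - lat) / 2.0)
            ) - amp / (1.0 + np.exp(lat / 2.0))
    return env


def generate_session(config: GeneratorConfig) -> SessionRecording:
    """Generate one synthetic session.

    Per trial, band-limited oscillators and 1/f noise form the innovation
    input of a vector autoregression whose off-diagonal lag terms are the
    configured directed couplings; the evoked potential (forward-modelled
    from the configured CSD sink profile) is added on top for
    stimulus-onset-locked epochs.  A baseline tensor (condition-independent
    oscillators + noise) and, optionally, an MUA-envelope tensor accompany
    the LFP.  Identical seed and config give bit-identical output; trial
    content is drawn from per-trial counter-split substreams, so it does
    not depend on trial order.
    """
    config.validate()
    if config.couplings:
        _check_stability(config)
    n_cond = config.n_trials_per_condition
    conditions = np.repeat(CONDITIONS, n_cond)
    n_trials = conditions.size
    n_total = config.n_channels * len(config.probes)
    probe_of_channel = np.repeat(list(config.probes), config.n_channels)
    probe_slice = {
        p: slice(i * config.n_channels, (i + 1) * config.n_channels)
        for i, p in enumerate(config.probes)
    }

    max_lag = max((c.lag for c in config.couplings), default=1)
    burn = 128 + max_lag
    n_full = config.n_samples + burn

    # pre-designed band-pass filters per (oscillator, condition)
    sos_cache = {}
    for k, osc in enumerate(config.oscillators):
        for cond in CONDITIONS:
            f0 = osc.f0 + _cond(osc.df, cond, 0.0)
            sos_cache[k, cond] = _bandpass_sos(f0, osc.bandwidth, config.fs)

    streams = np.random.SeedSequence(config.seed).spawn(n_trials + 1)
    session_rng = np.random.default_rng(streams[-1])

    innovations = np.zeros((n_trials, n_total, n_full))
    baseline = np.zeros((n_trials, n_total, config.n_baseline_samples))
    for i in range(n_trials):
        rng = np.random.default_rng(streams[i])
        cond = conditions[i]
        u = _one_over_f(rng, n_total, n_full,
                        config.noise.exponent, config.noise.sd)
        b = _one_over_f(rng, n_total, config.n_baseline_samples,
                        config.noise.exponent, config.noise.sd)
        for k, osc in enumerate(config.oscillators):
            prof = (np.ones(config.n_channels) if osc.depth_profile is None
                    else np.asarray(osc.depth_profile, dtype=float))
            drive = signal.sosfilt(sos_cache[k, cond], rng.standard_normal(n_full))
            drive /= max(drive.std(), 1e-12)   # unit RMS: amplitude is in µV
            g = osc.amplitude * _cond(osc.gain, cond, 1.0)
            u[probe_slice[osc.probe]] += g * prof[:, None] * drive[None, :]
            # baseline carries the oscillator at neutral gain, no condition effect
            bdrive = signal.sosfilt(
                _bandpass_sos(osc.f0, osc.bandwidth, config.fs),
                rng.standard_normal(config.n_baseline_samples),
            )
            bdrive /= max(bdrive.std(), 1e-12)
            b[probe_slice[osc.probe]] += osc.amplitude * prof[:, None] * bdrive[None, :]
        innovations[i] = u
        baseline[i] = b

    # drive the coupling VAR, grouped by condition
    lfp_full = innovations.copy()
    if config.couplings:
        for cond in CONDITIONS:
            rows = np.flatnonzero(conditions == cond)
            a = _coupling_matrices(config, cond)
            x = lfp_full[rows]  # (n, ch, t) view copy semantics: fancy index copies
            for t in range(max_lag, n_full):
                acc = x[:, :, t]
                for k in range(a.shape[0]):
                    acc += x[:, :, t - k - 1] @ a[k].T
            lfp_full[rows] = x
    lfp = lfp_full[:, :, burn:]

    if config.evoked is not None and config.epoch_alignment == "stimulus_onset":
        ev = _evoked_potentials(config)
        for p in config.probes:
            lfp[:, probe_slice[p], :] += ev[None, :, :]

    mua = None
    if config.evoked is not None and config.with_mua:
        base_env = _mua_envelope(config, session_rng)
        mua = np.tile(base_env[None, :, :], (n_trials, 1, 1))
        mua += 0.02 * np.abs(
            session_rng.standard_normal((n_trials, n_total, config.n_samples))
        )

    return SessionRecording(
        lfp=lfp,
        fs=config.fs,
        probe_of_channel=probe_of_channel,
        condition=conditions,
        spacing_um=config.spacing_um,
        epoch_alignment=config.epoch_alignment,
        baseline=baseline,
        mua_envelope=mua,
        ground_truth=config,
        seed=config.seed,
    )
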