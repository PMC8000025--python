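"""Epoch extraction and bipolar re-referencing.

Epoching is a pure view into the stored per-trial traces: no filtering or
detrending happens here (per-trial mean removal is done by the spectral
and Granger stages at consumption time).  Bipolar re-referencing takes the
first difference of adjacent contacts within each probe
(superficial minus deep), which cancels any signal common to a whole
probe and sharpens spatial specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .session import BipolarRecording, SessionRecording


@dataclass
class EpochSpec:
    """Window definition relative to an alignment event.

    ``event_sample`` is the sample index of the alignment event within the
    stored trace; the extracted window starts ``start_offset`` samples
    after it (negative = before) and is ``length`` samples long.  The
    default baseline window runs from 200 ms before to 30 ms after
    stimulus onset.
    """

    alignment: str = "stimulus_onset"
    start_offset: int = 0
    length: int = 512
    event_sample: int = 0
    baseline_start_ms: float = -200.0
    baseline_end_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("epoch length must be positive")

    def duration_ms(self, fs: float) -> float:
        return 1000.0 * self.length / fs

    def baseline_n_samples(self, fs: float) -> int:
        return int(round((self.baseline_end_ms - self.baseline_start_ms) / 1000.0 * fs))


def epoch(recording: SessionRecording, spec: EpochSpec) -> SessionRecording:
    """Extract per-trial windows of exactly ``spec.length`` samples.

    Sample 0 of the result corresponds to ``event_sample + start_offset``
    in the source trace.  Windows exceeding the trace bounds raise, naming
    the offending trials.
    """
    start = spec.event_sample + spec.start_offset
    stop = start + spec.length
    if start < 0 or stop > recording.n_samples:
        raise ValueError(
            f"epoch window [{start}, {stop}) exceeds data bounds "
            f"[0, {recording.n_samples}) for trials "
            f"{list(range(recording.n_trials))}"
        )
    out = SessionRecording(
        lfp=recording.lfp[:, :, start:stop].copy(),
        fs=recording.fs,
        probe_of_channel=recording.probe_of_channel.copy(),
        condition=recording.condition.copy(),
        spacing_um=recording.spacing_um,
        epoch_alignment=spec.alignment,
        referencing=recording.referencing,
        channel_position=recording.channel_position.copy(),
        baseline=recording.baseline,
        mua_envelope=recording.mua_envelope,
        ground_truth=recording.ground_truth,
        seed=recording.seed,
    )
    return out


def bipolar_rereference(recording: SessionRecording) -> BipolarRecording:
    """Adjacent-contact bipolar derivations, superficial minus deep.

    Each probe's contacts are ordered by position (superficial first);
    derivation d_i = v_i - v_{i+1} sits at the parents' midpoint position.
    Derivations never span probes; a single-contact probe is an error.
    Adding one common time series to every contact of a probe leaves the
    result exactly unchanged.
    """
    if recording.referencing == "bipolar":
        raise ValueError("recording is already bipolar-referenced")
    lfp_parts, base_parts, mua_parts = [], [], []
    probe_labels, positions = [], []
    for probe in recording.probes():
        ch = recording.channels(probe)
        if ch.size < 2:
            raise ValueError(f"probe {probe} has fewer than 2 contacts")
        order = ch[np.argsort(recording.channel_position[ch])]
        pos = recording.channel_position[order]
        lfp_parts.append(recording.lfp[:, order[:-1], :] - recording.lfp[:, order[1:], :])
        if recording.baseline is not None:
            base_parts.append(
                recording.baseline[:, order[:-1], :] - recording.baseline[:, order[1:], :]
            )
        probe_labels.extend([probe] * (ch.size - 1))
        positions.extend((pos[:-1] + pos[1:]) / 2.0)
    return BipolarRecording(
        lfp=np.concatenate(lfp_parts, axis=1),
        fs=recording.fs,
        probe_of_channel=np.asarray(probe_labels),
        condition=recording.condition.copy(),
        spacing_um=recording.spacing_um,
        epoch_alignment=recording.epoch_alignment,
        referencing="bipolar",
        channel_position=np.asarray(positions, dtype=float),
        baseline=np.concatenate(base_parts, axis=1) if base_parts else None,
        ground_truth=recording.ground_truth,
        seed=recording.seed,
    )
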