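"""Trial-epoched laminar recording containers.

A :class:`SessionRecording` holds the LFP tensor for one recording session:
``lfp[trial, channel, sample]`` in microvolts, together with the probe
geometry (which area each contact belongs to, its position along the probe)
and the per-trial attention condition labels.  Channels are indexed globally
across both probes; within a probe, position 0 is the most superficial
contact and positions increase with depth in units of the inter-contact
spacing.  Bipolar derivations carry fractional (midpoint) positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CONDITIONS = ("RF", "OUT1", "OUT2")
PROBES = ("V1", "V4")


@dataclass
class SessionRecording:
    """One session of trial-epoched multichannel laminar LFP.

    Parameters
    ----------
    lfp : ndarray, shape (n_trials, n_channels, n_samples)
        Epoched LFP in µV.
    fs : float
        Sampling rate in Hz.
    probe_of_channel : ndarray of str, shape (n_channels,)
        Area label ("V1" or "V4") per channel.
    condition : ndarray of str, shape (n_trials,)
        Attention condition per trial ("RF", "OUT1" or "OUT2").
    spacing_um : float
        Inter-contact spacing in µm.
    channel_position : ndarray, optional
        Position of each contact along its probe in spacing units
        (0 = most superficial).  Defaults to 0..k-1 per probe.  Bipolar
        derivations use half-integer midpoints.
    baseline : ndarray, optional
        Companion pre-stimulus tensor (n_trials, n_channels, n_baseline).
    mua_envelope : ndarray, optional
        Multiunit-activity envelope (n_trials, n_channels, n_samples),
        nonnegative; used for response-latency based laminar alignment.
    ground_truth : object, optional
        The generator configuration that produced a synthetic session.
    """

    lfp: np.ndarray
    fs: float
    probe_of_channel: np.ndarray
    condition: np.ndarray
    spacing_um: float = 150.0
    epoch_alignment: str = "stimulus_onset"
    referencing: str = "monopolar"
    channel_position: Optional[np.ndarray] = None
    baseline: Optional[np.ndarray] = None
    mua_envelope: Optional[np.ndarray] = None
    ground_truth: object = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        if self.lfp.ndim != 3:
            raise ValueError("lfp must be (n_trials, n_channels, n_samples)")
        self.probe_of_channel = np.asarray(self.probe_of_channel, dtype="U8")
        self.condition = np.asarray(self.condition, dtype="U8")
        if self.probe_of_channel.shape[0] != self.lfp.shape[1]:
            raise ValueError("probe_of_channel length must match channel count")
        if self.condition.shape[0] != self.lfp.shape[0]:
            raise ValueError("condition length must match trial count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.lfp).all():
            raise ValueError("lfp contains non-finite samples")
        if self.channel_position is None:
            pos = np.empty(self.n_channels, dtype=float)
            for probe in np.unique(self.probe_of_channel):
                idx = np.flatnonzero(self.probe_of_channel == probe)
                pos[idx] = np.arange(idx.size, dtype=float)
            self.channel_position = pos
        else:
            self.channel_position = np.asarray(self.channel_position, dtype=float)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[2]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs

    def channels(self, probe: str) -> np.ndarray:
        """Global indices of the contacts belonging to ``probe``."""
        return np.flatnonzero(self.probe_of_channel == probe)

    def trials(self, condition: str) -> np.ndarray:
        """Trial indices carrying the given condition label."""
        return np.flatnonzero(self.condition == condition)

    def probes(self) -> tuple:
        seen = []
        for p in self.probe_of_channel:
            if p not in seen:
                seen.append(p)
        return tuple(seen)


class BipolarRecording(SessionRecording):
    """A :class:`SessionRecording` of adjacent-contact bipolar derivations.

    Each derivation is the superficial-minus-deep first difference of two
    adjacent parent contacts of the same probe and carries their midpoint
    position; a probe with k contacts yields k - 1 derivations.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        self.referencing = "bipolar"
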