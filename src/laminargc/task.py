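"""Behavioral-task bookkeeping and window arithmetic.

Small worked-example helpers for the quantities a laminar attention study
reports about its own design: percent-correct from trial counts, the
number of distinct task conditions from the randomized factors (cue
color, dimming order, grating motion direction), the duration of an
N-sample analysis window, and the multitaper half-bandwidth W = TW / T.
"""

from __future__ import annotations


def percent_correct(n_correct: int, n_total: int) -> float:
    """Behavioral performance in percent, disregarding excluded trials."""
    if n_total <= 0 or n_correct < 0 or n_correct > n_total:
        raise ValueError("need 0 <= n_correct <= n_total with n_total > 0")
    return 100.0 * n_correct / n_total


def condition_count(n_cue_colors: int = 3, n_dimming_orders: int = 6,
                    n_motion_directions: int = 2) -> int:
    """Total number of task conditions from the randomized factor levels."""
    return n_cue_colors * n_dimming_orders * n_motion_directions


def window_duration_ms(n_samples: int = 512, fs: float = 1017.375) -> float:
    """Duration of an N-sample window in ms (512 at 1017.375 Hz = 503.25)."""
    return 1000.0 * n_samples / fs


def half_bandwidth_hz(tw: float = 2.0, n_samples: int = 512,
                      fs: float = 1017.375) -> float:
    """Multitaper spectral half-bandwidth W = TW / T in Hz (about 4)."""
    return tw * fs / n_samples


def frequency_resolution_hz(n_samples: int = 512, fs: float = 1017.375) -> float:
    """Frequency grid step fs / N in Hz (about 2)."""
    return fs / n_samples
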