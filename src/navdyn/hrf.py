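"""Hemodynamic response function and event-stream convolution.

The kernel is the standard double-gamma shape (response gamma with shape 6,
undershoot gamma with shape 16, both scale 1 s, undershoot ratio 1/6),
truncated at 32 s and peak-normalized to 1. Event streams sampled at 10 Hz
are convolved causally at their native resolution and only then sampled at
acquisition frame times, preserving sub-TR event timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma

from .errors import AlignmentError, InvalidConfigError

HRF_SUPPORT_S: float = 32.0


@dataclass(frozen=True)
class HRFKernel:
    dt_s: float
    values: np.ndarray

    @property
    def peak_time_s(self) -> float:
        return float(np.argmax(self.values) * self.dt_s)


def canonical_hrf(
    dt_s: float = 0.1,
    response_shape: float = 6.0,
    undershoot_shape: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> HRFKernel:
    """Double-gamma HRF sampled every ``dt_s`` seconds over 32 s."""
    if dt_s <= 0:
        raise InvalidConfigError("dt_s must be positive")
    t = np.arange(0.0, HRF_SUPPORT_S + dt_s / 2, dt_s)
    h = _gamma.pdf(t, response_shape) - undershoot_ratio * _gamma.pdf(
        t, undershoot_shape
    )
    h = h / np.max(h)
    return HRFKernel(dt_s=dt_s, values=h)


def convolve_stream(stream: np.ndarray, hrf: HRFKernel) -> np.ndarray:
    """Causal convolution of a stream with the HRF at the stream's resolution.

    The stream is zero-padded before its onset (nothing precedes the
    navigation window), and the output is truncated to the stream's length.
    """
    full = np.convolve(np.asarray(stream, dtype=float), hrf.values)
    return full[: len(stream)] * hrf.dt_s


def build_regressor(
    stream: np.ndarray,
    hrf: HRFKernel,
    frame_times_s: np.ndarray,
    sampling: str = "onset",
    tr_s: float = 2.0,
) -> np.ndarray:
    """HRF-convolved stream sampled at acquisition frame times.

    ``frame_times_s`` are relative to the stream onset. ``sampling`` picks
    the frame onset (default) or midpoint as the read-out time.
    """
    stream = np.asarray(stream, dtype=float)
    t_stream = np.arange(stream.size) * hrf.dt_s
    times = np.asarray(frame_times_s, dtype=float)
    if sampling == "midpoint":
        times = times + tr_s / 2.0
    if times.min() < -1e-9 or times.max() > t_stream[-1] + hrf.dt_s + 1e-9:
        raise AlignmentError("frame times fall outside the stream's time grid")
    conv = convolve_stream(stream, hrf)
    return np.interp(times, t_stream, conv)
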