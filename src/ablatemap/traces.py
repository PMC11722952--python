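"""Per-cell trace processing: smoothing, dF/F, threshold event detection.

The relative change dF/F = (F_t - F0) / F0 is computed against a
pre-stimulus baseline F0 (mean of the smoothed trace over the last 9.5 s
before stimulation). Events are called when dF/F exceeds 15 baseline
standard deviations — a deliberately conservative threshold appropriate
for the large-amplitude responses of interest here.

Conventions (documented once, used throughout): smoothing precedes the
dF/F computation; the threshold applies to the dF/F series, with the SD
taken over the baseline window of that same series; threshold crossings
use strict inequality; the stimulus onset frame is
``floor(onset_s * frame_rate)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import StimulusProtocol

__all__ = [
    "BaselineStats",
    "EventResult",
    "smooth",
    "compute_dff",
    "detect_event",
    "time_to_peak",
    "first_responding_train",
    "SMOOTH_KERNEL",
]

# 3-point Gaussian window sampled at offsets {-1, 0, +1} with sigma = 0.65,
# normalized to sum 1 (approx [0.2389, 0.5222, 0.2389]).
_g = np.exp(-np.arange(-1, 2) ** 2 / (2 * 0.65**2))
SMOOTH_KERNEL: np.ndarray = _g / _g.sum()
del _g

DEFAULT_BASELINE_WINDOW = 9.5  # s
DEFAULT_K_SD = 15.0


@dataclass(frozen=True)
class BaselineStats:
    """Pre-stimulus baseline over ``[t_start, t_stop)`` seconds."""

    t_start: float
    t_stop: float
    f0: float  # mean smoothed fluorescence, intensity units
    sd: float  # SD of smoothed fluorescence over the window
    sd_dff: float  # SD of the dF/F series over the window


@dataclass(frozen=True)
class EventResult:
    """Outcome of threshold event detection on one dF/F trace."""

    detected: bool
    onset_frame: int | None  # first frame with dff > threshold
    peak_frame: int | None  # argmax of post-stimulus dff
    peak_dff: float | None
    threshold: float


def smooth(trace: np.ndarray) -> np.ndarray:
    """Convolve with the normalized 3-point Gaussian window.

    Reflective end handling; output length equals input length. Linear
    and shift-equivariant: ``smooth(a*x + b) = a*smooth(x) + b``.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("smooth requires a 1-D trace of length >= 3")
    padded = np.concatenate([x[1:2], x, x[-2:-1]])
    return np.convolve(padded, SMOOTH_KERNEL, mode="valid")


def compute_dff(trace: np.ndarray, frame_rate: float,
                stimulus_onset: float,
                baseline_window: float = DEFAULT_BASELINE_WINDOW,
                ) -> tuple[np.ndarray, BaselineStats]:
    """Smooth a raw trace and convert it to dF/F.

    F0 is the mean of the smoothed trace over
    ``[stimulus_onset - baseline_window, stimulus_onset)``; every frame
    then maps to ``(F_t - F0) / F0``.

    Raises if the recording does not span the baseline window before the
    stimulus, or if F0 is not positive.
    """
    f = smooth(trace)
    onset_frame = int(np.floor(stimulus_onset * frame_rate))
    start_frame = int(np.floor((stimulus_onset - baseline_window) * frame_rate))
    if start_frame < 0 or onset_frame <= start_frame:
        raise ValueError(
            f"insufficient pre-stimulus data for a {baseline_window} s baseline"
        )
    if onset_frame > f.size:
        raise ValueError("stimulus onset beyond the end of the trace")
    base = f[start_frame:onset_frame]
    f0 = float(base.mean())
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:.3g} must be positive for dF/F")
    dff = (f - f0) / f0
    stats = BaselineStats(
        t_start=stimulus_onset - baseline_window, t_stop=stimulus_onset,
        f0=f0, sd=float(base.std()),
        sd_dff=float(dff[start_frame:onset_frame].std()),
    )
    return dff, stats


def detect_event(dff: np.ndarray, baseline: BaselineStats,
                 frame_rate: float, stimulus_onset: float,
                 k_sd: float = DEFAULT_K_SD) -> EventResult:
    """Threshold event detection on a dF/F trace.

    An event is called iff any post-stimulus sample strictly exceeds
    ``k_sd`` times the baseline dF/F standard deviation. The onset is the
    first crossing frame and the peak the argmax over post-stimulus
    frames.
    """
    dff = np.asarray(dff, dtype=float)
    if baseline.sd_dff <= 0:
        raise ValueError(
            "baseline dF/F SD is zero; the threshold is undefined — add a "
            "noise floor or use traces with measurement noise"
        )
    thr = k_sd * baseline.sd_dff
    onset_frame = int(np.floor(stimulus_onset * frame_rate))
    post = dff[onset_frame:]
    above = post > thr
    if not above.any():
        return EventResult(False, None, None, None, thr)
    first = onset_frame + int(np.argmax(above))
    peak = onset_frame + int(np.argmax(post))
    return EventResult(True, first, peak, float(dff[peak]), thr)


def time_to_peak(event: EventResult, frame_rate: float,
                 stimulus_onset: float) -> float:
    """Seconds from stimulus onset to the detected dF/F peak.

    Raises if no event was detected (the peak time is undefined).
    """
    if not event.detected or event.peak_frame is None:
        raise ValueError("time_to_peak is undefined without a detected event")
    onset_frame = int(np.floor(stimulus_onset * frame_rate))
    return (event.peak_frame - onset_frame) / frame_rate


def first_responding_train(dff: np.ndarray, baseline: BaselineStats,
                           protocol: StimulusProtocol, frame_rate: float,
                           k_sd: float = DEFAULT_K_SD) -> int | None:
    """Smallest train index within whose window the dF/F first crosses threshold.

    The window of 1-based train ``k`` is ``[t_k, t_{k+1})`` (the last
    train's window has the same duration). Returns None if the trace never
    crosses inside any train window.
    """
    dff = np.asarray(dff, dtype=float)
    if baseline.sd_dff <= 0:
        raise ValueError("baseline dF/F SD is zero; threshold undefined")
    thr = k_sd * baseline.sd_dff
    crossing = np.flatnonzero(dff > thr)
    if crossing.size == 0:
        return None
    times = crossing / frame_rate
    for k in range(1, protocol.n_trains + 1):
        t0 = protocol.train_time(k)
        t1 = t0 + 1.0 / protocol.train_rate
        hit = times[(times >= t0) & (times < t1)]
        if hit.size:
            return k
    return None
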