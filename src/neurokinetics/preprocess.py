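"""Inertial-speed computation, condition windowing, spike binning/smoothing.

Inertial speed is the behavioural backbone of every coupling analysis: the
mean across the six IMU channels of the absolute first temporal difference,
kept in arbitrary inertial units at 200 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import InertialTrace, InjectionEvent, SessionRecording, SpeedSeries

log = logging.getLogger(__name__)

#: default analysis-window offsets (minutes relative to the relevant injection)
DEFAULT_OFFSETS = {
    "BL": (-25.0, -5.0),  # before the first injection
    "V": (5.0, 25.0),
    "K": (5.0, 25.0),
    "LD": (65.0, 85.0),
    "LD->K": (5.0, 25.0),  # after the ketamine that follows L-DOPA
    "LD-early": (35.0, 55.0),
}


class WindowError(ValueError):
    """Requested condition window cannot be resolved for this session."""


@dataclass(frozen=True)
class ConditionWindow:
    label: str
    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if self.end_min <= self.start_min:
            raise WindowError(f"window {self.label}: end must exceed start")

    @property
    def start_s(self) -> float:
        return self.start_min * 60.0

    @property
    def end_s(self) -> float:
        return self.end_min * 60.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def compute_inertial_speed(imu: InertialTrace) -> SpeedSeries:
    """Mean over the 6 channels of |x[t+1] − x[t]|; output has n−1 samples.

    The speed sample at index t represents the interval [t, t+1]; it is
    invariant to a constant offset on any channel and non-negative by
    construction.
    """
    if imu.n_samples < 2:
        raise ValueError("need at least 2 IMU samples to differentiate")
    speed = np.mean(np.abs(np.diff(imu.data, axis=0)), axis=1)
    return SpeedSeries(values=speed, fs=imu.fs)


def resolve_condition_windows(
    events: list[InjectionEvent],
    duration_min: float,
    offsets: dict[str, tuple[float, float]] | None = None,
    include_ld_early: bool = False,
) -> list[ConditionWindow]:
    """Map a session's injection sequence to its fixed analysis windows.

    Session types: vehicle→ketamine (windows BL, V, K), L-DOPA→vehicle
    (BL, LD) and L-DOPA→ketamine (BL, LD→K).  The baseline window precedes
    the first injection and is clipped at the session start with a warning.
    """
    off = dict(DEFAULT_OFFSETS)
    if offsets:
        off.update(offsets)
    if not events:
        raise WindowError("no injection events")
    ev = sorted(events, key=lambda e: e.time_min)
    drugs = tuple(e.drug for e in ev)

    windows: list[ConditionWindow] = []
    t0 = ev[0].time_min
    bl_start, bl_end = t0 + off["BL"][0], t0 + off["BL"][1]
    if bl_start < 0:
        warnings.warn(
            f"baseline window clipped at session start ([{bl_start:.1f}, {bl_end:.1f}] min)"
        )
        bl_start = 0.0
    if bl_end > bl_start:
        windows.append(ConditionWindow("BL", bl_start, bl_end))

    if drugs == ("vehicle", "ketamine"):
        windows.append(_window("V", ev[0].time_min, off["V"]))
        windows.append(_window("K", ev[1].time_min, off["K"]))
    elif drugs == ("L-DOPA", "vehicle"):
        windows.append(_window("LD", ev[0].time_min, off["LD"]))
        if include_ld_early:
            windows.append(_window("LD-early", ev[0].time_min, off["LD-early"]))
    elif drugs == ("L-DOPA", "ketamine"):
        windows.append(_window("LD->K", ev[1].time_min, off["LD->K"]))
        if include_ld_early:
            windows.append(_window("LD-early", ev[0].time_min, off["LD-early"]))
    else:
        raise WindowError(
            f"unrecognised session type {drugs!r}; expected vehicle->ketamine, "
            "L-DOPA->vehicle or L-DOPA->ketamine"
        )

    too_long = [w.label for w in windows if w.end_min > duration_min]
    if too_long:
        raise WindowError(
            f"session of {duration_min:g} min too short for windows {too_long}"
        )
    return windows


def _window(label: str, injection_min: float, offset: tuple[float, float]) -> ConditionWindow:
    return ConditionWindow(label, injection_min + offset[0], injection_min + offset[1])


def bin_spike_counts(
    spike_times: np.ndarray, bin_s: float, window: tuple[float, float] | ConditionWindow
) -> np.ndarray:
    """Spike counts in left-closed right-open bins tiling the window."""
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    if isinstance(window, ConditionWindow):
        start, end = window.start_s, window.end_s
    else:
        start, end = window
    n_bins = int(np.floor((end - start) / bin_s + 1e-9))
    edges = start + bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts.astype(np.int64)


def smooth_counts(counts: np.ndarray, window_ms: float, bin_ms: float = 5.0) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    ``window_ms`` is rounded to an integer number of bins (logged when it is
    not already a multiple of ``bin_ms``).  Output keeps the input length and
    timebase, so the mean is preserved up to edge effects.
    """
    counts = np.asarray(counts, dtype=np.float64)
    w = int(round(window_ms / bin_ms))
    if abs(w * bin_ms - window_ms) > 1e-9:
        log.info("smoothing window %.4g ms rounded to %d bins", window_ms, w)
    if w < 1:
        raise ValueError("smoothing window shorter than one bin")
    if w > counts.size:
        raise ValueError(
            f"smoothing window of {w} bins longer than series of {counts.size}"
        )
    # O(n) sliding sum via cumulative sums; edge windows shrink to the
    # available samples, which preserves a constant input exactly
    n = counts.size
    left = w // 2
    right = w - 1 - left
    cs = np.concatenate([[0.0], np.cumsum(counts)])
    hi = np.minimum(np.arange(n) + right + 1, n)
    lo = np.maximum(np.arange(n) - left, 0)
    return (cs[hi] - cs[lo]) / (hi - lo)


def downsample_lfp(x: np.ndarray, fs_in: float, fs_out: float = 500.0) -> np.ndarray:
    """Anti-aliased decimation of a raw LFP trace to the analysis rate.

    Zero-phase 8th-order Chebyshev-I low-pass then decimation (integer
    factor required).
    """
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"non-integer decimation factor {factor:g}")
    factor = int(round(factor))
    if factor == 1:
        return np.asarray(x, dtype=np.float64)
    return signal.decimate(np.asarray(x, dtype=np.float64), factor, n=8, zero_phase=True)


def frame_average_speed(
    speed: SpeedSeries,
    window: tuple[float, float] | ConditionWindow,
    frame_s: float = 1.0,
    hop_s: float = 0.5,
    n_frames: int | None = None,
) -> np.ndarray:
    """Average speed within each analysis frame of a spectrogram.

    Frame k spans [start + k·hop, start + k·hop + frame); the return has one
    value per frame, matched to the spectrogram of the same window.
    """
    if isinstance(window, ConditionWindow):
        start, end = window.start_s, window.end_s
    else:
        start, end = window
    if n_frames is None:
        n_frames = int(np.floor(((end - start) - frame_s) / hop_s)) + 1
    out = np.empty(n_frames)
    for k in range(n_frames):
        seg = speed.slice(start + k * hop_s, start + k * hop_s + frame_s)
        out[k] = seg.mean() if seg.size else np.nan
    return out
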