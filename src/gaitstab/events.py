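"""Gait-event detection and cycle segmentation.

Initial contact (IC) and toe-off (TO) are detected from the anteroposterior
axis of a shank-mounted accelerometer: IC as the prominent positive peak
that initiates stance, TO as the deepest trough between consecutive ICs.
The first and last three gait cycles are trimmed as acceleration/
deceleration transients and ten consecutive cycles are extracted for the
stability metrics.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError, SegmentationError
from .types import GaitEvents, StrideSeries, TriaxialSignal


def estimate_stride_frequency(x: np.ndarray, fs: float,
                              fmin: float = 0.3, fmax: float = 2.0) -> float:
    """Dominant frequency of the demeaned signal within [fmin, fmax] Hz.

    For a shank AP signal the fundamental is the stride frequency (one IC
    peak per stride).
    """
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= fmin) & (freqs <= fmax)
    if not band.any() or not np.any(spec[band] > 0):
        raise SegmentationError("cannot estimate stride frequency: empty band")
    return float(freqs[band][np.argmax(spec[band])])


def detect_gait_events(shank_ap: np.ndarray, fs: float,
                       prominence_factor: float = 0.5,
                       min_distance_strides: float = 0.5) -> GaitEvents:
    """Detect IC and TO events from shank AP acceleration.

    IC peaks are located with a minimum inter-peak distance of
    ``min_distance_strides`` / (estimated stride frequency) and a prominence
    threshold of ``prominence_factor`` times the robust (MAD-based) SD of the
    signal.  TO is the minimum of the signal within the middle 30-90% of each
    IC-to-IC interval.  Detection parameters are recorded in the output
    ``meta`` for provenance.
    """
    x = np.asarray(shank_ap, float)
    if fs < 50:
        raise ParameterError("fs must be at least 50 Hz for event detection")
    if np.ptp(x) == 0:
        raise SegmentationError("constant signal: no gait events detectable")
    robust_sd = 1.4826 * np.median(np.abs(x - np.median(x)))
    if robust_sd == 0:
        robust_sd = np.std(x)
    f_stride = estimate_stride_frequency(x, fs)
    min_dist = max(int(round(min_distance_strides / f_stride * fs)), 1)
    prominence = prominence_factor * robust_sd
    ic, _ = find_peaks(x, distance=min_dist, prominence=prominence)
    # refinement: IC peaks are the *prominent* positive peaks; drop candidates
    # far below the typical detected peak height (spurious noise maxima)
    if len(ic) >= 2:
        height_floor = 0.5 * float(np.median(x[ic]))
        ic = ic[x[ic] >= height_floor]
    if len(ic) < 2:
        raise SegmentationError(
            f"only {len(ic)} initial contacts detected; need at least 2")
    to = []
    for a, b in zip(ic[:-1], ic[1:]):
        lo = a + int(0.3 * (b - a))
        hi = a + int(0.9 * (b - a))
        seg = x[lo:hi]
        if len(seg) == 0:
            raise SegmentationError("degenerate IC interval during TO search")
        to.append(lo + int(np.argmin(seg)))
    return GaitEvents(
        ic_indices=np.asarray(ic), to_indices=np.asarray(to), fs=fs,
        meta={"stride_freq_estimate": f_stride,
              "min_peak_distance_samples": min_dist,
              "prominence": prominence},
    )


def trim_transient_strides(events: GaitEvents, n_head: int = 3,
                           n_tail: int = 3) -> GaitEvents:
    """Drop the first ``n_head`` and last ``n_tail`` gait cycles.

    Removes the acceleration and deceleration transients at the ends of a
    walkway pass.
    """
    if n_head < 0 or n_tail < 0:
        raise ParameterError("n_head/n_tail must be non-negative")
    n_cycles = events.n_cycles
    if n_head == n_tail == 0:
        return events
    # a trimmed recording must keep at least two full cycles to be analyzable
    if n_cycles < n_head + n_tail + 2:
        raise SegmentationError(
            f"{n_cycles} cycles cannot be trimmed by {n_head}+{n_tail}")
    ic = events.ic_indices[n_head: len(events.ic_indices) - n_tail]
    lo, hi = ic[0], ic[-1]
    to = events.to_indices[(events.to_indices > lo) & (events.to_indices < hi)]
    return GaitEvents(ic_indices=ic, to_indices=to, fs=events.fs,
                      meta=dict(events.meta, trimmed=(n_head, n_tail)))


def extract_cycles(signal: TriaxialSignal, events: GaitEvents,
                   n_cycles: int = 10) -> StrideSeries:
    """Extract a window of ``n_cycles`` consecutive cycles from the signal.

    The window starts at the first (post-trim) IC and spans exactly
    ``n_cycles`` IC-to-IC cycles.
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be at least 1")
    if events.n_cycles < n_cycles:
        raise SegmentationError(
            f"requested {n_cycles} cycles but only {events.n_cycles} available")
    ic = events.ic_indices[: n_cycles + 1]
    start, stop = int(ic[0]), int(ic[-1])
    if stop > signal.n_samples:
        raise SegmentationError("events extend beyond signal length")
    boundaries = ic - start
    return StrideSeries(
        fs=signal.fs,
        ap=signal.ap[start:stop].copy(),
        ml=signal.ml[start:stop].copy(),
        vt=signal.vt[start:stop].copy(),
        boundaries=np.asarray(boundaries),
        meta={"start_sample": start, "stop_sample": stop},
    )


def gait_speed(traverse_time_s: float, distance_m: float = 10.0) -> float:
    """Average gait speed over a walkway of known length (m/s)."""
    if traverse_time_s <= 0:
        raise ParameterError("traverse time must be positive")
    if distance_m <= 0:
        raise ParameterError("distance must be positive")
    return distance_m / traverse_time_s
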