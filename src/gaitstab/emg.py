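"""EMG envelopes, co-contraction indices and sagittal joint-angle curves.

These produce the even-surface biomechanical predictors used alongside the
trunk-acceleration stability features: normalized muscle-activation
envelopes for five lower-limb muscles (TA, SOL, RF, BF, GM), stance/swing
co-contraction indices for the shank (TA-SOL) and thigh (RF-BF) pairs, and
100-point gait-cycle-normalized joint-angle curves with named extrema,
including the ankle dorsiflexion angle at initial contact (Ang_IC_ankle).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import NormalizationError, ParameterError
from .types import GaitEvents

EMG_BAND = (20.0, 500.0)  # Hz
EMG_LOWPASS = 10.0        # Hz envelope smoothing
ANGLE_LOWPASS = 6.0       # Hz, zero-lag 4th-order (order-2 applied twice)


@dataclass
class EmgEnvelope:
    fs: float
    channel: str
    amplitude: np.ndarray  # normalized to subject max, values in [0, 1]


@dataclass
class CycleCurve:
    """A 100-point gait-cycle-normalized curve with its stance/swing split."""

    values: np.ndarray
    stance_end: int  # index of the first swing sample
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.values) != 100:
            raise ParameterError(f"cycle curve must have 100 points, got {len(self.values)}")
        if not (0 < self.stance_end < 100):
            raise ParameterError("stance_end must lie inside the cycle")

    def phase(self, which: str) -> np.ndarray:
        if which == "stance":
            return self.values[: self.stance_end]
        if which == "swing":
            return self.values[self.stance_end:]
        raise ParameterError(f"phase must be 'stance' or 'swing', got {which!r}")


def _butter_filtfilt(x: np.ndarray, fs: float, cutoff, btype: str,
                     order: int = 2) -> np.ndarray:
    b, a = butter(order, np.asarray(cutoff) / (fs / 2), btype=btype)
    return filtfilt(b, a, x)


def emg_envelope(raw: np.ndarray, fs: float, channel: str = "") -> EmgEnvelope:
    """Linear-envelope chain: bandpass 20-500 Hz, mean-center, full-wave
    rectify, lowpass 10 Hz, normalize to the subject's maximum amplitude.

    If ``fs`` cannot support the 500 Hz band edge the band is clipped just
    below Nyquist with a warning.
    """
    x = np.asarray(raw, float)
    if fs <= 2 * EMG_BAND[0]:
        raise ParameterError(f"fs={fs} too low for a {EMG_BAND[0]} Hz highpass")
    hi = EMG_BAND[1]
    if fs <= 2 * EMG_BAND[1]:
        hi = 0.95 * fs / 2
        warnings.warn(
            f"fs={fs} Hz cannot represent the {EMG_BAND[1]} Hz band edge; "
            f"clipping bandpass to {hi:.0f} Hz", stacklevel=2)
    x = _butter_filtfilt(x, fs, (EMG_BAND[0], hi), "bandpass")
    x = x - x.mean()
    x = np.abs(x)
    env = _butter_filtfilt(x, fs, EMG_LOWPASS, "lowpass")
    env = np.clip(env, 0.0, None)
    peak = env.max()
    # numerical residue of filtering a DC/zero signal is not activity
    floor = 1e-10 * max(1.0, float(np.max(np.abs(raw))))
    if peak <= floor:
        raise NormalizationError("all-zero envelope: cannot normalize to maximum")
    return EmgEnvelope(fs=fs, channel=channel, amplitude=env / peak)


def cocontraction_index(e1: CycleCurve | np.ndarray, e2: CycleCurve | np.ndarray,
                        phase: str = "stance") -> float:
    """Co-contraction index (percent): overlap of two normalized envelopes.

    CI = 100 * 2 * sum(min(e1, e2)) / sum(e1 + e2) over the phase samples.
    Symmetric in its arguments and invariant to common scaling.  Returns NaN
    (flagged missing) when both envelopes are zero throughout the phase.
    """
    if isinstance(e1, CycleCurve) and isinstance(e2, CycleCurve):
        if e1.stance_end != e2.stance_end:
            raise ParameterError("cycle curves disagree on the stance/swing split")
        a, b = e1.phase(phase), e2.phase(phase)
    else:
        a, b = np.asarray(e1, float), np.asarray(e2, float)
        if a.shape != b.shape:
            raise ParameterError("envelopes must have equal length")
    denom = float(np.sum(a + b))
    if denom == 0:
        return float("nan")
    return float(100.0 * 2.0 * np.sum(np.minimum(a, b)) / denom)


def filter_angles(raw: np.ndarray, fs: float, cutoff: float = ANGLE_LOWPASS) -> np.ndarray:
    """Zero-lag 4th-order Butterworth lowpass (order 2 applied forward and
    backward) for joint-angle series."""
    if fs <= 2 * cutoff:
        raise ParameterError(f"fs={fs} too low for a {cutoff} Hz lowpass")
    x = np.asarray(raw, float)
    if len(x) < 15:  # filtfilt default pad length for order 2
        raise ParameterError("series shorter than the filter pad length")
    return _butter_filtfilt(x, fs, cutoff, "lowpass")


def time_normalize(series: np.ndarray, events: GaitEvents,
                   n_points: int = 100) -> CycleCurve:
    """Average all IC-to-IC cycles of a series onto a 100-point cycle curve.

    The stance/swing boundary is the mean toe-off phase across cycles.
    Averaging per-cycle curves is linear, so the mean curve of pooled
    strides equals the mean of per-trial means with equal stride counts.
    """
    x = np.asarray(series, float)
    bounds = events.cycle_bounds()
    if not bounds:
        raise ParameterError("no complete cycles in events")
    grid = np.linspace(0.0, 1.0, n_points, endpoint=False)
    curves = []
    to_phases = []
    for a, b in bounds:
        seg = x[a:b]
        if len(seg) < 2:
            raise ParameterError("degenerate cycle segment")
        curves.append(np.interp(grid, np.linspace(0, 1, len(seg)), seg))
        inside = events.to_indices[(events.to_indices > a) & (events.to_indices < b)]
        if len(inside):
            to_phases.append((inside[0] - a) / (b - a))
    mean_curve = np.mean(curves, axis=0)
    stance_frac = float(np.mean(to_phases)) if to_phases else 0.6
    stance_end = int(np.clip(round(stance_frac * n_points), 1, n_points - 1))
    return CycleCurve(values=mean_curve, stance_end=stance_end,
                      meta={"n_cycles": len(curves), "stance_fraction": stance_frac})


def peak_angles(curve: CycleCurve, joint: str = "ankle") -> dict[str, float]:
    """Named extrema of a joint-angle cycle curve.

    Always includes the value at initial contact (cycle index 0) —
    ``Ang_IC_<joint>`` — plus stance/swing maxima and minima.
    """
    v = curve.values
    st, sw = curve.phase("stance"), curve.phase("swing")
    return {
        f"Ang_IC_{joint}": float(v[0]),
        f"Ang_max_stance_{joint}": float(st.max()),
        f"Ang_min_stance_{joint}": float(st.min()),
        f"Ang_max_swing_{joint}": float(sw.max()),
        f"Ang_min_swing_{joint}": float(sw.min()),
    }
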