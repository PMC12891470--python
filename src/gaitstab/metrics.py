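"""Linear and nonlinear trunk-acceleration stability metrics.

Six metric families are computed per axis (AP/ML/VT) over a window of ten
consecutive gait cycles:

RMS
    Root-mean-square of the demeaned acceleration normalized by squared
    gait speed — the linear variability magnitude.
HR
    Harmonic ratio: even-to-odd (AP, VT) or odd-to-even (ML) ratio of
    harmonic amplitudes at integer multiples of the stride frequency —
    smoothness / step symmetry.  AP and VT movement repeats every step
    (two per stride), so a smooth gait concentrates their energy at even
    stride harmonics; ML alternates left/right and repeats per stride.
SampEn
    Sample entropy: -ln of the conditional probability that template
    sequences matching for m points (Chebyshev distance <= r) also match
    for m+1 — signal irregularity.
RQA %REC / %DET
    Recurrence rate and determinism of the time-delay-embedded signal —
    periodicity of the state-space trajectory.
sLE
    Short-term maximum Lyapunov exponent by the Rosenstein
    nearest-neighbor divergence method on the time-normalized
    (100 samples/stride) window — local dynamic stability.

All metrics demean their input, so they are invariant to a constant
offset; HR, SampEn, RQA and sLE are additionally invariant to amplitude
scaling, while RMS scales linearly with amplitude by design.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, SegmentationError
from .events import extract_cycles
from .types import GaitEvents, StrideSeries, TriaxialSignal

#: axis name mapping between signal containers (lower) and feature names (upper)
AXIS_LABELS = {"ap": "AP", "ml": "ML", "vt": "VT"}


@dataclass
class MetricConfig:
    """Tunable parameters of the stability metrics.

    Defaults follow field conventions: SampEn with m=2, r=0.2*SD;
    RQA embedding dimension 5, delay 10 samples, radius 0.4x the RMS
    amplitude of the embedded trajectory, minimum diagonal 2; Rosenstein
    sLE on 100-samples-per-stride normalized time with the divergence
    slope fitted over the first half stride; HR over 20 harmonics.
    """

    sampen_m: int = 2
    sampen_r: float = 0.2
    rqa_dim: int = 5
    rqa_delay: int = 10
    rqa_radius_factor: float = 0.4
    rqa_min_diag: int = 2
    sle_dim: int = 5
    sle_delay: int = 10
    sle_samples_per_stride: int = 100
    sle_fit_fraction: float = 0.5
    hr_n_harmonics: int = 20

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val <= 0:
                raise ParameterError(f"{name} must be positive, got {val}")
        if not (0 < self.sle_fit_fraction <= 1):
            raise ParameterError("sle_fit_fraction must be in (0, 1]")


@dataclass
class StabilityFeatures:
    """Named stability-metric values for one subject/window.

    ``values`` maps canonical feature names (RMS_VT, SampEn_AP, ...) to
    floats; metrics whose estimate is undefined on the given window are NaN
    and listed in ``missing``.  The configuration that produced the values
    travels with them for provenance.
    """

    values: dict[str, float]
    config: MetricConfig
    missing: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def rms_normalized(window: np.ndarray, speed: float) -> float:
    """RMS of the demeaned window divided by squared gait speed."""
    if speed <= 0:
        raise ParameterError("gait speed must be positive")
    x = np.asarray(window, float)
    x = x - x.mean()
    return float(np.sqrt(np.mean(x**2)) / speed**2)


def harmonic_amplitudes(window: np.ndarray, stride_freq: float, fs: float,
                        n_harmonics: int = 20) -> np.ndarray:
    """Amplitude of the signal at the first ``n_harmonics`` integer multiples
    of the stride frequency, by direct evaluation of the DFT sum at each
    harmonic frequency (harmonics above Nyquist get zero amplitude)."""
    if stride_freq <= 0 or fs <= 0:
        raise ParameterError("stride_freq and fs must be positive")
    x = np.asarray(window, float)
    x = x - x.mean()
    n = len(x)
    t = np.arange(n) / fs
    amps = np.zeros(n_harmonics)
    for k in range(1, n_harmonics + 1):
        f = k * stride_freq
        if f >= fs / 2:
            break
        z = np.sum(x * np.exp(-2j * np.pi * f * t))
        amps[k - 1] = 2.0 * np.abs(z) / n
    return amps


def harmonic_ratio(window: np.ndarray, stride_freq: float, fs: float,
                   axis: str = "AP", n_harmonics: int = 20) -> float:
    """Even/odd (AP, VT) or odd/even (ML) harmonic amplitude ratio.

    Returns ``inf`` when the denominator sum is numerically zero (perfectly
    one-sided spectrum) — flagged degenerate by the caller.
    """
    axis = axis.upper()
    if axis not in ("AP", "ML", "VT"):
        raise ParameterError(f"axis must be AP/ML/VT, got {axis!r}")
    amps = harmonic_amplitudes(window, stride_freq, fs, n_harmonics)
    even = amps[1::2].sum()  # harmonics 2, 4, 6, ...
    odd = amps[0::2].sum()   # harmonics 1, 3, 5, ...
    num, den = (odd, even) if axis == "ML" else (even, odd)
    if den <= 1e-12 * max(num, 1.0):
        return math.inf
    return float(num / den)


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2,
                   r: float | None = None) -> float:
    """Sample entropy (nats): -ln(A/B) with Chebyshev template matching.

    A and B count (m+1)- and m-length template pairs within tolerance
    ``r`` (default ``r_factor * SD(x)``); self-matches are excluded.
    A constant series returns 0 (all templates match); B=0 returns NaN
    (undefined, flagged missing by the caller).
    """
    x = np.asarray(x, float)
    n = len(x)
    if m < 1:
        raise ParameterError("m must be >= 1")
    if n < m + 2:
        raise ParameterError(f"series too short for m={m}: n={n}")
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    if r is None:
        r = r_factor * sd
    if r <= 0:
        raise ParameterError("tolerance r must be positive")
    n_t = n - m  # templates indexable for both m and m+1 comparisons
    diff = np.abs(x[:, None] - x[None, :])
    d_m = diff[:n_t, :n_t].copy()
    for k in range(1, m):
        np.maximum(d_m, diff[k:k + n_t, k:k + n_t], out=d_m)
    d_m1 = np.maximum(d_m, diff[m:m + n_t, m:m + n_t])
    iu = np.triu_indices(n_t, k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    if b == 0:
        return math.nan
    if a == 0:
        return math.inf
    return float(-math.log(a / b))


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = len(x) - (dim - 1) * delay
    if n < 2:
        raise ParameterError(
            f"series of length {len(x)} too short for dim={dim}, delay={delay}")
    return np.column_stack([x[k * delay: k * delay + n] for k in range(dim)])


def rqa(x: np.ndarray, config: MetricConfig | None = None) -> tuple[float, float]:
    """Recurrence rate and determinism (%REC, %DET) of the embedded signal.

    The recurrence matrix uses Euclidean distance with radius
    ``radius_factor`` times the RMS amplitude of the (centered) embedded
    trajectory; pairs within a Theiler window equal to the embedding delay
    are excluded.  %DET is the fraction of recurrent points lying on
    diagonal lines of length >= ``rqa_min_diag``.
    """
    cfg = config or MetricConfig()
    x = np.asarray(x, float)
    x = x - x.mean()
    emb = _embed(x, cfg.rqa_dim, cfg.rqa_delay)
    n = len(emb)
    theiler = cfg.rqa_delay
    if n <= theiler + cfg.rqa_min_diag:
        raise ParameterError("series too short for the requested RQA embedding")
    center = emb - emb.mean(axis=0)
    radius = cfg.rqa_radius_factor * float(np.sqrt(np.mean(np.sum(center**2, axis=1))))
    dist = cdist(emb, emb)
    rec = dist <= radius

    n_recurrent = 0
    n_allowed = 0
    n_in_lines = 0
    n_recurrent_det = 0  # recurrent points on diagonals long enough for lines
    lmin = cfg.rqa_min_diag
    # upper-triangle diagonals beyond the Theiler window; symmetric, so the
    # single-triangle ratios equal the full-matrix ones
    for off in range(theiler + 1, n):
        diag = np.diagonal(rec, offset=off)
        n_allowed += len(diag)
        n_recurrent += int(diag.sum())
        if len(diag) < lmin:
            continue  # cannot host a line of length lmin: excluded from %DET
        n_recurrent_det += int(diag.sum())
        # run-length encode recurrent stretches on this diagonal
        padded = np.concatenate([[0], diag.astype(np.int8), [0]])
        edges = np.flatnonzero(np.diff(padded))
        runs = edges[1::2] - edges[::2]
        n_in_lines += int(runs[runs >= lmin].sum())
    if n_allowed == 0:
        raise ParameterError("Theiler window excludes every pair")
    p_rec = 100.0 * n_recurrent / n_allowed
    p_det = (math.nan if n_recurrent_det == 0
             else 100.0 * n_in_lines / n_recurrent_det)
    return p_rec, p_det


def time_normalize_strides(x: np.ndarray, boundaries: np.ndarray,
                           samples_per_stride: int = 100) -> np.ndarray:
    """Resample each stride (boundary-to-boundary segment) to a fixed number
    of samples and concatenate, removing the speed/cadence confound."""
    boundaries = np.asarray(boundaries, int)
    if len(boundaries) < 2:
        raise ParameterError("need at least one stride (two boundaries)")
    out = []
    grid = np.linspace(0.0, 1.0, samples_per_stride, endpoint=False)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if b - a < 2:
            raise ParameterError("degenerate stride segment")
        seg = x[a:b]
        src = np.linspace(0.0, 1.0, len(seg))
        out.append(np.interp(grid, src, seg))
    return np.concatenate(out)


def short_term_lyapunov(x: np.ndarray, boundaries: np.ndarray,
                        config: MetricConfig | None = None) -> float:
    """Short-term maximum Lyapunov exponent (nats/stride), Rosenstein method.

    The window is time-normalized to ``sle_samples_per_stride`` samples per
    stride, delay-embedded, and each point is paired with its nearest
    neighbor at least one mean period away in time.  The slope of the mean
    log-divergence curve over the first ``sle_fit_fraction`` of a stride,
    expressed per stride, is the exponent.  Returns NaN when no valid
    neighbor pairs exist.
    """
    cfg = config or MetricConfig()
    y = time_normalize_strides(np.asarray(x, float), boundaries,
                               cfg.sle_samples_per_stride)
    y = y - y.mean()
    emb = _embed(y, cfg.sle_dim, cfg.sle_delay)
    n = len(emb)
    period = cfg.sle_samples_per_stride
    if n <= 2 * period:
        return math.nan
    dist = cdist(emb, emb)
    idx = np.arange(n)
    too_close = np.abs(idx[:, None] - idx[None, :]) <= period
    dist[too_close] = np.inf
    nn = np.argmin(dist, axis=1)
    has_nn = np.isfinite(dist[idx, nn])

    k_max = int(round(cfg.sle_fit_fraction * period))
    log_div = np.full(k_max + 1, math.nan)
    eps = 1e-12
    for k in range(k_max + 1):
        valid = has_nn & (idx + k < n) & (nn + k < n)
        if not valid.any():
            break
        d = np.linalg.norm(emb[idx[valid] + k] - emb[nn[valid] + k], axis=1)
        log_div[k] = float(np.mean(np.log(np.maximum(d, eps))))
    ok = np.isfinite(log_div)
    if ok.sum() < 2:
        return math.nan
    k_axis = np.flatnonzero(ok)
    slope = np.polyfit(k_axis, log_div[ok], 1)[0]
    return float(slope * period)  # per-sample slope -> per stride


def compute_all(signal: TriaxialSignal, events: GaitEvents, speed: float,
                config: MetricConfig | None = None,
                n_cycles: int = 10) -> StabilityFeatures:
    """Compute all 18 stability features (6 metrics x 3 axes) on a window of
    ``n_cycles`` consecutive gait cycles."""
    cfg = config or MetricConfig()
    strides = extract_cycles(signal, events, n_cycles=n_cycles)
    return compute_from_strides(strides, speed, cfg)


def compute_from_strides(strides: StrideSeries, speed: float,
                         config: MetricConfig | None = None) -> StabilityFeatures:
    cfg = config or MetricConfig()
    values: dict[str, float] = {}
    missing: list[str] = []
    f_stride = strides.stride_freq
    for ax, label in AXIS_LABELS.items():
        w = strides.axis(ax)
        try:
            values[f"RMS_{label}"] = rms_normalized(w, speed)
            values[f"HR_{label}"] = harmonic_ratio(
                w, f_stride, strides.fs, axis=label, n_harmonics=cfg.hr_n_harmonics)
            values[f"SampEn_{label}"] = sample_entropy(
                w, m=cfg.sampen_m, r_factor=cfg.sampen_r)
            p_rec, p_det = rqa(w, cfg)
            values[f"RQA_rec_{label}"] = p_rec
            values[f"RQA_det_{label}"] = p_det
            values[f"sLE_{label}"] = short_term_lyapunov(w, strides.boundaries, cfg)
        except (ParameterError, SegmentationError) as exc:
            raise type(exc)(f"axis {label}: {exc}") from exc
    for name, val in values.items():
        if not np.isfinite(val):
            missing.append(name)
    return StabilityFeatures(values=values, config=cfg, missing=missing,
                             meta={"stride_freq": f_stride, "speed": speed,
                                   "n_cycles": strides.n_cycles})
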