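"""Synthetic gait cohorts with known ground truth.

Real trunk-accelerometry cohorts of people with stroke are not freely
shareable, so every downstream stage of the pipeline is exercised against
signals and tables generated here, where the generative parameters are known
exactly and can be recovered by independent fits.

Three generators are provided:

``simulate_trunk_acceleration``
    A periodic triaxial trunk-acceleration signal built as a sum of
    harmonics of the stride frequency, with cycle-to-cycle timing jitter and
    additive Gaussian noise.  Anteroposterior (AP) and vertical (VT) energy
    sits mainly at even multiples of the stride frequency (one step per half
    stride), mediolateral (ML) energy at odd multiples — the structure the
    harmonic ratio quantifies.

``simulate_classification_cohort``
    A tabular subjects-by-features cohort (default 71 stroke-like vs 39
    control-like) with standardized mean shifts of ``effect_size_d`` injected
    on RMS_VT, RMS_AP, RMS_ML and SampEn_AP (up) and HR_AP (down) — the
    direction observed for post-stroke gait on uneven ground.

``simulate_regression_cohort``
    An even-surface-predictors to uneven-surface-targets table for stroke-like
    walkers embedding three interpretable nonlinearities: a gait-speed
    breakpoint (default 0.8 m/s) below which uneven-surface speed drops
    disproportionately, a U-shaped dependence of uneven-surface SampEn_AP on
    ankle dorsiflexion angle at initial contact, and a plateau (default 1.5)
    of uneven-surface HR_AP in its even-surface value.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import GROUP_HC, GROUP_PWS, TriaxialSignal

EMG_CHANNELS = ("TA", "SOL", "RF", "BF", "GM")
ANGLE_CHANNELS = ("ankle", "knee", "hip")

#: Step-1 stability feature names: 6 metric families x 3 axes
STABILITY_FEATURES = tuple(
    f"{m}_{ax}"
    for m in ("RMS", "HR", "SampEn", "RQA_rec", "RQA_det", "sLE")
    for ax in ("AP", "ML", "VT")
)

#: features carrying the injected group effect and its sign
EFFECT_FEATURES = {
    "RMS_VT": +1.0,
    "RMS_AP": +1.0,
    "RMS_ML": +1.0,
    "SampEn_AP": +1.0,
    "HR_AP": -1.0,
}

# healthy-control marginal (mean, SD) for each stability feature; units as in
# the feature glossary (RMS normalized by squared speed, RQA in percent, ...)
_HC_MARGINALS = {
    "RMS_AP": (1.6, 0.50), "RMS_ML": (1.4, 0.45), "RMS_VT": (1.8, 0.55),
    "HR_AP": (2.2, 0.50), "HR_ML": (1.9, 0.45), "HR_VT": (2.4, 0.55),
    "SampEn_AP": (0.90, 0.25), "SampEn_ML": (0.95, 0.25), "SampEn_VT": (0.85, 0.25),
    "RQA_rec_AP": (8.0, 3.0), "RQA_rec_ML": (9.0, 3.0), "RQA_rec_VT": (8.0, 3.0),
    "RQA_det_AP": (88.0, 6.0), "RQA_det_ML": (85.0, 7.0), "RQA_det_VT": (90.0, 5.0),
    "sLE_AP": (0.60, 0.20), "sLE_ML": (0.65, 0.20), "sLE_VT": (0.55, 0.20),
}

# demographics: (HC mean, HC sd, PwS mean, PwS sd); no group effect injected
_DEMOGRAPHICS = {
    "age": (65.6, 7.4, 63.8, 14.2),
    "height": (162.7, 8.5, 164.8, 7.5),
    "weight": (60.4, 8.5, 64.1, 11.2),
    "bmi": (22.8, 2.2, 23.6, 3.6),
}


@dataclass
class CohortSpec:
    """Parameters defining a synthetic cohort.

    ``effect_size_d`` is the standardized (Cohen's d) group difference
    injected on each effect-carrying feature; the 0.65-0.75 range reported
    for RMS metrics on uneven ground motivates the 0.7 default.
    """

    n_pws: int = 71
    n_hc: int = 39
    seed: int = 0
    effect_size_d: float = 0.7
    fs: float = 100.0
    stride_freq_mean: dict[str, float] = field(
        default_factory=lambda: {GROUP_HC: 1.0, GROUP_PWS: 0.85}
    )
    noise_sd: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            GROUP_HC: {"even": 0.10, "uneven": 0.16},
            GROUP_PWS: {"even": 0.22, "uneven": 0.32},
        }
    )
    breakpoint_speed: float = 0.8
    hr_plateau: float = 1.5
    ushape_center: float = 5.0  # deg ankle dorsiflexion at initial contact

    def __post_init__(self) -> None:
        if self.n_pws <= 0 or self.n_hc <= 0:
            raise ParameterError("group sizes must be positive")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if not np.isfinite(self.effect_size_d):
            raise ParameterError("effect_size_d must be finite")
        if not (0.2 <= self.breakpoint_speed <= 1.4):
            raise ParameterError("breakpoint_speed outside the generated speed range")


@dataclass
class SubjectRecord:
    """One synthetic subject: signals plus ground-truth generative metadata."""

    subject_id: str
    group: str
    surface: str
    trunk: TriaxialSignal
    shank_ap: np.ndarray
    emg: dict[str, np.ndarray]
    emg_fs: float
    angles: dict[str, np.ndarray]
    gait_time_10m: float
    truth: dict[str, Any] = field(default_factory=dict)

    @property
    def gait_speed(self) -> float:
        return 10.0 / self.gait_time_10m


def default_harmonics(odd_weight: float = 1.0) -> dict[str, dict[int, float]]:
    """Per-axis harmonic amplitude templates (harmonic index -> amplitude).

    AP/VT carry step-frequency (even-harmonic) energy; ML carries
    stride-frequency (odd-harmonic) energy.  ``odd_weight`` scales the
    off-pattern amplitudes of AP/VT (and the even ones of ML): 1.0 gives a
    control-like harmonic ratio around 3, larger values degrade periodic
    structure the way hemiparetic gait does.
    """
    w = odd_weight
    return {
        "ap": {1: 0.22 * w, 2: 0.90, 3: 0.10 * w, 4: 0.28, 5: 0.05 * w, 6: 0.09},
        "vt": {1: 0.25 * w, 2: 1.20, 3: 0.12 * w, 4: 0.35, 5: 0.06 * w, 6: 0.12},
        "ml": {1: 0.80, 2: 0.16 * w, 3: 0.22, 4: 0.06 * w, 5: 0.07, 6: 0.03 * w},
    }


def _stride_boundaries(n_strides: int, stride_freq: float, jitter: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Cumulative stride-boundary times with multiplicative duration jitter."""
    base = 1.0 / stride_freq
    durations = base * np.clip(1.0 + jitter * rng.standard_normal(n_strides), 0.5, 1.5)
    return np.concatenate([[0.0], np.cumsum(durations)])


def _phase(t: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Continuous stride phase: integer at each stride boundary."""
    k = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(bounds) - 2)
    return k + (t - bounds[k]) / (bounds[k + 1] - bounds[k])


def simulate_trunk_acceleration(
    stride_freq: float,
    n_strides: int = 20,
    fs: float = 100.0,
    seed: int = 0,
    harmonics: dict[str, dict[int, float]] | None = None,
    jitter: float = 0.02,
    noise_sd: float = 0.1,
    amplitude_scale: float = 1.0,
) -> TriaxialSignal:
    """Simulate a triaxial trunk-acceleration signal (m/s^2).

    The signal is a sum of cosines at integer multiples of the stride
    frequency, evaluated on a jittered per-stride phase so that timing
    variability propagates into spectral blur, plus white Gaussian noise.
    Ground-truth initial-contact and toe-off times (phase 0 and 0.6 of each
    stride) are stored in ``meta`` for event-detection validation.
    """
    if fs <= 0 or stride_freq <= 0:
        raise ParameterError("fs and stride_freq must be positive")
    if fs < 50:
        raise ParameterError("fs must be at least 50 Hz")
    if n_strides < 16:
        raise ParameterError("need at least 16 strides (3+3 trimmed, >=10 analyzed)")
    rng = np.random.default_rng(seed)
    harmonics = harmonics if harmonics is not None else default_harmonics()

    bounds = _stride_boundaries(n_strides, stride_freq, jitter, rng)
    n = int(np.floor(bounds[-1] * fs))
    t = np.arange(n) / fs
    phi = _phase(t, bounds)

    axes = {}
    for ax in ("ap", "ml", "vt"):
        phases = rng.uniform(0, 2 * np.pi, size=max(harmonics[ax]) + 1)
        x = np.zeros(n)
        for h, amp in harmonics[ax].items():
            x += amplitude_scale * amp * np.cos(2 * np.pi * h * phi + phases[h])
        x += noise_sd * rng.standard_normal(n)
        axes[ax] = x

    ic_times = bounds[:-1]
    to_times = bounds[:-1] + 0.6 * np.diff(bounds)
    return TriaxialSignal(
        fs=fs, ap=axes["ap"], ml=axes["ml"], vt=axes["vt"],
        meta={"ic_times": ic_times, "to_times": to_times,
              "stride_bounds": bounds, "stride_freq": stride_freq},
    )


def simulate_shank_ap(
    ic_times: np.ndarray,
    to_times: np.ndarray,
    n_samples: int,
    fs: float,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> np.ndarray:
    """Shank anteroposterior acceleration: a sharp positive peak at each
    initial contact and a negative trough at each toe-off."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)
    for tc in np.asarray(ic_times):
        x += 3.0 * np.exp(-0.5 * ((t - tc) / 0.030) ** 2)
    for tc in np.asarray(to_times):
        x -= 2.0 * np.exp(-0.5 * ((t - tc) / 0.040) ** 2)
    return x + noise_sd * rng.standard_normal(n_samples)


def _simulate_emg(bounds: np.ndarray, duration: float, emg_fs: float,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-muscle bursts at fixed phases of each stride, carrier-band noise."""
    burst_phase = {"TA": (0.55, 0.15), "SOL": (0.25, 0.15), "RF": (0.05, 0.10),
                   "BF": (0.90, 0.10), "GM": (0.15, 0.12)}
    n = int(duration * emg_fs)
    t = np.arange(n) / emg_fs
    out = {}
    for ch, (center, width) in burst_phase.items():
        env = np.zeros(n)
        for k in range(len(bounds) - 1):
            tc = bounds[k] + center * (bounds[k + 1] - bounds[k])
            w = width * (bounds[k + 1] - bounds[k])
            env += np.exp(-0.5 * ((t - tc) / w) ** 2)
        carrier = rng.standard_normal(n)  # broadband interference-pattern carrier
        out[ch] = env * carrier + 0.02 * rng.standard_normal(n)
    return out


def _simulate_angles(bounds: np.ndarray, n: int, fs: float, ankle_ic: float,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    t = np.arange(n) / fs
    phi = _phase(t, bounds)
    return {
        # ankle crosses its IC value at integer phase
        "ankle": ankle_ic + 10.0 * np.sin(2 * np.pi * phi) - 5.0 * np.sin(4 * np.pi * phi)
        + 0.3 * rng.standard_normal(n),
        "knee": 30.0 - 25.0 * np.cos(2 * np.pi * phi) + 0.3 * rng.standard_normal(n),
        "hip": 15.0 * np.sin(2 * np.pi * phi + 0.5) + 0.3 * rng.standard_normal(n),
    }


def simulate_subject(
    spec: CohortSpec,
    group: str,
    surface: str = "even",
    subject_id: str = "S000",
    seed: int = 0,
    n_strides: int = 20,
) -> SubjectRecord:
    """Generate a full synthetic subject (trunk + shank signals, EMG, angles).

    Stroke-like subjects walk slower, with more timing jitter, more noise,
    larger harmonic amplitudes and degraded AP even/odd harmonic structure —
    so that metrics computed from the *signal* reproduce the group
    differences the tabular generator injects directly.
    """
    if group not in (GROUP_HC, GROUP_PWS):
        raise ParameterError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    pws = group == GROUP_PWS
    stride_freq = spec.stride_freq_mean[group] * (1 + 0.04 * rng.standard_normal())
    jitter = 0.05 if pws else 0.02
    odd_weight = float(np.clip((2.6 if pws else 1.0) + 0.3 * rng.standard_normal(), 0.3, 5.0))
    amp_scale = (1.35 if pws else 1.0) * (1 + 0.10 * rng.standard_normal())
    noise = spec.noise_sd[group][surface]
    if surface == "uneven":
        jitter *= 1.5

    trunk = simulate_trunk_acceleration(
        stride_freq=stride_freq, n_strides=n_strides, fs=spec.fs,
        seed=int(rng.integers(2**31)), harmonics=default_harmonics(odd_weight),
        jitter=jitter, noise_sd=noise, amplitude_scale=amp_scale,
    )
    shank = simulate_shank_ap(
        trunk.meta["ic_times"], trunk.meta["to_times"], trunk.n_samples, spec.fs,
        noise_sd=0.15, seed=int(rng.integers(2**31)),
    )
    speed_mean, speed_sd = (0.75, 0.18) if pws else (1.20, 0.12)
    if surface == "uneven":
        speed_mean *= 0.85
    speed = float(np.clip(speed_mean + speed_sd * rng.standard_normal(), 0.3, 2.0))
    ankle_ic = spec.ushape_center + (6.0 if pws else 3.0) * rng.standard_normal()

    emg_fs = 1000.0
    emg = _simulate_emg(trunk.meta["stride_bounds"], trunk.duration, emg_fs, rng)
    angles = _simulate_angles(trunk.meta["stride_bounds"], trunk.n_samples, spec.fs,
                              ankle_ic, rng)
    return SubjectRecord(
        subject_id=subject_id, group=group, surface=surface, trunk=trunk,
        shank_ap=shank, emg=emg, emg_fs=emg_fs, angles=angles,
        gait_time_10m=10.0 / speed,
        truth={"stride_freq": stride_freq, "jitter": jitter, "odd_weight": odd_weight,
               "amplitude_scale": amp_scale, "noise_sd": noise, "speed": speed,
               "ankle_ic": ankle_ic, "ic_times": trunk.meta["ic_times"],
               "to_times": trunk.meta["to_times"]},
    )


def simulate_classification_cohort(
    spec: CohortSpec,
    include_signals: bool = False,
    n_strides: int = 20,
) -> tuple[pd.DataFrame, dict[str, Any], list[SubjectRecord]]:
    """Tabular stroke-vs-control cohort with injected standardized effects.

    Returns ``(features, truth, records)`` where ``features`` has one row per
    subject (stability features + demographics + ``group``), ``truth`` records
    the generative marginals and effect sizes, and ``records`` holds full
    signal-level subjects when ``include_signals`` is set (empty list
    otherwise).
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.effect_size_d
    groups = [GROUP_PWS] * spec.n_pws + [GROUP_HC] * spec.n_hc
    rows = []
    for i, g in enumerate(groups):
        row: dict[str, Any] = {"subject_id": f"S{i:03d}", "group": g}
        for feat in STABILITY_FEATURES:
            mu, sd = _HC_MARGINALS[feat]
            shift = d * sd * EFFECT_FEATURES.get(feat, 0.0) if g == GROUP_PWS else 0.0
            val = mu + shift + sd * rng.standard_normal()
            if feat.startswith("RQA"):
                val = float(np.clip(val, 0.0, 100.0))
            row[feat] = val
        for dem, (m_hc, s_hc, m_pws, s_pws) in _DEMOGRAPHICS.items():
            m, s = (m_pws, s_pws) if g == GROUP_PWS else (m_hc, s_hc)
            row[dem] = m + s * rng.standard_normal()
        rows.append(row)
    features = pd.DataFrame(rows)

    records: list[SubjectRecord] = []
    if include_signals:
        for i, g in enumerate(groups):
            records.append(
                simulate_subject(spec, g, "even", subject_id=f"S{i:03d}",
                                 seed=int(rng.integers(2**31)), n_strides=n_strides)
            )
    truth = {
        "effect_size_d": d,
        "effect_features": dict(EFFECT_FEATURES),
        "hc_marginals": dict(_HC_MARGINALS),
        "n_pws": spec.n_pws, "n_hc": spec.n_hc,
    }
    return features, truth, records


def simulate_regression_cohort(
    spec: CohortSpec,
    n: int = 71,
    noise_scale: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Even-surface predictors -> uneven-surface targets for stroke-like walkers.

    Embedded structure (all recoverable by brute-force fits):

    * ``uneven_speed = even_speed - 0.15 - 0.5*max(0, bp - even_speed) + eps``
      — continuous piecewise-linear with a kink at ``bp = breakpoint_speed``;
      slow walkers lose disproportionately more speed on uneven ground.
    * ``uneven_RMS_VT`` is elevated and flat below the breakpoint, declining
      linearly above it.
    * ``uneven_SampEn_AP`` is quadratic in ankle dorsiflexion at initial
      contact with its minimum at ``ushape_center``.
    * ``uneven_HR_AP = min(even_HR_AP, hr_plateau) + eps``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    bp = spec.breakpoint_speed
    even_speed = rng.uniform(0.3, 1.3, n)
    ang = spec.ushape_center + 6.0 * rng.standard_normal(n)
    even_hr = rng.uniform(0.8, 2.2, n)
    even_rms = 2.0 + 0.5 * rng.standard_normal(n)
    even_sampen = 1.0 + 0.25 * rng.standard_normal(n)
    even_sle = 0.7 + 0.2 * rng.standard_normal(n)
    ci_stance = 30.0 + 8.0 * rng.standard_normal(n)
    age = 63.8 + 14.2 * rng.standard_normal(n)

    ns = noise_scale
    relu = lambda z: np.maximum(z, 0.0)  # noqa: E731
    params = {
        "breakpoint_speed": bp, "speed_offset": 0.15, "below_slope_extra": 0.5,
        "speed_noise_sd": 0.06 * ns,
        "rms_base": 2.2, "rms_decline": 1.2, "rms_noise_sd": 0.15 * ns,
        "ushape_center": spec.ushape_center, "ushape_quadratic": 0.004,
        "sampen_base": 0.9, "sampen_noise_sd": 0.10 * ns,
        "hr_plateau": spec.hr_plateau, "hr_noise_sd": 0.08 * ns,
    }
    uneven_speed = (even_speed - params["speed_offset"]
                    - params["below_slope_extra"] * relu(bp - even_speed)
                    + params["speed_noise_sd"] * rng.standard_normal(n))
    uneven_rms = (params["rms_base"] + 0.3 * (even_rms - 2.0)
                  - params["rms_decline"] * relu(even_speed - bp)
                  + params["rms_noise_sd"] * rng.standard_normal(n))
    uneven_sampen = (params["sampen_base"]
                     + params["ushape_quadratic"] * (ang - spec.ushape_center) ** 2
                     + 0.3 * (even_sampen - 1.0)
                     + params["sampen_noise_sd"] * rng.standard_normal(n))
    uneven_hr = (np.minimum(even_hr, spec.hr_plateau)
                 + params["hr_noise_sd"] * rng.standard_normal(n))

    table = pd.DataFrame({
        "subject_id": [f"R{i:03d}" for i in range(n)],
        "even_speed": even_speed, "Ang_IC_ankle": ang, "even_HR_AP": even_hr,
        "even_RMS_VT": even_rms, "even_SampEn_AP": even_sampen,
        "even_sLE_AP": even_sle, "CI_stance_shank": ci_stance, "age": age,
        "uneven_speed": uneven_speed, "uneven_RMS_VT": uneven_rms,
        "uneven_SampEn_AP": uneven_sampen, "uneven_HR_AP": uneven_hr,
    })
    return table, params


#: predictor / target column names of the regression cohort
REGRESSION_PREDICTORS = ("even_speed", "Ang_IC_ankle", "even_HR_AP", "even_RMS_VT",
                         "even_SampEn_AP", "even_sLE_AP", "CI_stance_shank", "age")
REGRESSION_TARGETS = ("uneven_speed", "uneven_RMS_VT", "uneven_SampEn_AP", "uneven_HR_AP")
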