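"""Core in-memory containers shared across the pipeline.

Signals are thin dataclasses over numpy arrays; tabular data is plain
:class:`pandas.DataFrame` with a few reserved column names
(``subject_id``, ``group``, ``is_synthetic``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ParameterError

#: canonical axis names: anteroposterior, mediolateral, vertical
AXES = ("ap", "ml", "vt")

#: canonical group labels (healthy controls / people with stroke)
GROUP_HC = "HC"
GROUP_PWS = "PwS"


@dataclass
class TriaxialSignal:
    """Sampled triaxial trunk acceleration (m/s^2) at the L3 level.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz.
    ap, ml, vt : ndarray
        Equal-length acceleration series along the anteroposterior,
        mediolateral and vertical axes.
    meta : dict
        Free-form provenance (e.g. ground-truth event times for
        synthetic signals).
    """

    fs: float
    ap: np.ndarray
    ml: np.ndarray
    vt: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        self.vt = np.asarray(self.vt, dtype=float)
        n = len(self.ap)
        if not (len(self.ml) == len(self.vt) == n):
            raise ParameterError("ap/ml/vt series must have equal length")
        for name in AXES:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ParameterError(f"non-finite values in {name} axis")

    def axis(self, name: str) -> np.ndarray:
        if name not in AXES:
            raise ParameterError(f"unknown axis {name!r}; expected one of {AXES}")
        return getattr(self, name)

    @property
    def n_samples(self) -> int:
        return len(self.ap)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GaitEvents:
    """Initial-contact / toe-off sample indices defining gait cycles.

    Invariant: indices are strictly increasing and every toe-off lies strictly
    between the pair of initial contacts that brackets its cycle.
    """

    ic_indices: np.ndarray
    to_indices: np.ndarray
    fs: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ic_indices = np.asarray(self.ic_indices, dtype=int)
        self.to_indices = np.asarray(self.to_indices, dtype=int)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        for arr, name in ((self.ic_indices, "ic"), (self.to_indices, "to")):
            if len(arr) > 1 and not np.all(np.diff(arr) > 0):
                raise ParameterError(f"{name} indices must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return max(len(self.ic_indices) - 1, 0)

    def cycle_bounds(self) -> list[tuple[int, int]]:
        """(start, end) sample index of each IC-to-IC cycle."""
        ic = self.ic_indices
        return [(int(ic[i]), int(ic[i + 1])) for i in range(len(ic) - 1)]


@dataclass
class StrideSeries:
    """A window of consecutive gait cycles extracted from a triaxial signal."""

    fs: float
    ap: np.ndarray
    ml: np.ndarray
    vt: np.ndarray
    #: sample index (relative to the window start) of each cycle boundary,
    #: length n_cycles + 1, boundaries[0] == 0
    boundaries: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def axis(self, name: str) -> np.ndarray:
        if name not in AXES:
            raise ParameterError(f"unknown axis {name!r}")
        return getattr(self, name)

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    @property
    def stride_times(self) -> np.ndarray:
        return np.diff(self.boundaries) / self.fs

    @property
    def mean_stride_time(self) -> float:
        return float(np.mean(self.stride_times))

    @property
    def stride_freq(self) -> float:
        """Stride frequency (Hz) implied by the window: n_cycles / duration."""
        return self.n_cycles / (len(self.ap) / self.fs)
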