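"""Feature-table normalization and the design-stage power computation.

The normalization chain follows the pipeline's prescription: IQR-based
outlier replacement with the column median, Yeo-Johnson power
transformation of skewed features, then z-score standardization.  Every
transform is fit on the training split and applied with the stored
parameters to held-out data (:class:`TablePreprocessor`), so no test-set
statistic leaks into training.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import PowerTransformer

from .errors import NormalizationError, ParameterError


def iqr_impute(column: np.ndarray | pd.Series) -> np.ndarray:
    """Replace values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] by the
    pre-replacement median (quartiles by linear interpolation)."""
    x = np.asarray(column, float)
    if len(x) < 4:
        warnings.warn("fewer than 4 observations: IQR imputation skipped",
                      stacklevel=2)
        return x.copy()
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quartiles
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    med = np.median(x)
    out = x.copy()
    out[(x < lo) | (x > hi)] = med
    return out


def power_transform(column: np.ndarray | pd.Series,
                    lmbda: float | None = None) -> tuple[np.ndarray, float]:
    """Yeo-Johnson transform; lambda by maximum likelihood unless given.

    Returns ``(transformed, lambda)``.  A constant column passes through
    unchanged (with a warning) and reports lambda = 1.
    """
    x = np.asarray(column, float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("power_transform requires finite values")
    if np.ptp(x) == 0:
        warnings.warn("constant column: power transform skipped", stacklevel=2)
        return x.copy(), 1.0
    if lmbda is None:
        pt = PowerTransformer(method="yeo-johnson", standardize=False)
        out = pt.fit_transform(x[:, None])[:, 0]
        return out, float(pt.lambdas_[0])
    return stats.yeojohnson(x, lmbda=lmbda), float(lmbda)


def zscore(column: np.ndarray | pd.Series,
           mean: float | None = None, sd: float | None = None
           ) -> tuple[np.ndarray, float, float]:
    """Standardize; with ``mean``/``sd`` given, apply train parameters."""
    x = np.asarray(column, float)
    if mean is None or sd is None:
        mean, sd = float(np.mean(x)), float(np.std(x))
    if sd == 0:
        raise NormalizationError("constant column cannot be z-scored")
    return (x - mean) / sd, mean, sd


def correlation_prune(table: pd.DataFrame, threshold: float = 0.9
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Greedy multicollinearity reduction.

    While any absolute pairwise Pearson correlation >= ``threshold``
    remains, drop — from the currently worst pair — the member with the
    larger mean absolute correlation to all remaining columns.  Ties break
    on column order, so the procedure is deterministic.
    """
    if table.shape[1] < 2:
        raise ParameterError("correlation_prune needs at least 2 columns")
    cols = list(table.columns)
    corr = table[cols].corr().abs()
    dropped: list[str] = []
    while True:
        sub = corr.loc[cols, cols].copy()
        np.fill_diagonal(sub.values, 0.0)
        max_r = np.nanmax(sub.values) if len(cols) > 1 else 0.0
        if max_r < threshold:
            break
        i, j = np.unravel_index(np.nanargmax(sub.values), sub.shape)
        a, b = cols[i], cols[j]
        mean_a = sub.loc[a].mean()
        mean_b = sub.loc[b].mean()
        victim = a if mean_a >= mean_b else b
        cols.remove(victim)
        dropped.append(victim)
    return table[cols], dropped


def required_sample_size(effect_size_d: float, alpha: float = 0.05,
                         power: float = 0.8) -> int:
    """Smallest per-group n giving two-sided two-sample t-test power >= target.

    Power is the noncentral-t tail probability with noncentrality
    d * sqrt(n/2) and 2n - 2 degrees of freedom (equal groups).
    """
    if effect_size_d <= 0:
        raise ParameterError("effect size must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ParameterError("alpha and power must lie in (0, 1)")

    def attained(n: int) -> float:
        df = 2 * n - 2
        nc = effect_size_d * np.sqrt(n / 2.0)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))

    n = 2  # minimum feasible (df must be positive)
    while attained(n) < power:
        n += 1
        if n > 10**6:
            raise ParameterError("required sample size exceeds 1e6; check inputs")
    return n


@dataclass
class TablePreprocessor:
    """Fit-on-train / apply-on-test normalization for a feature table.

    Chain per column: IQR outlier replacement -> Yeo-Johnson -> z-score.
    Fitted parameters (lambda, mean, SD, fences) are stored so held-out
    data is transformed with *training* statistics only; applying the
    stored parameters twice to already-transformed data only re-centers
    with the same affine map, so the fit is reproducible and auditable.
    """

    columns: list[str] | None = None
    params: dict[str, dict[str, float]] = field(default_factory=dict)

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = self.columns or [c for c in table.columns
                                if pd.api.types.is_numeric_dtype(table[c])]
        self.columns = cols
        out = table.copy()
        for c in cols:
            x = iqr_impute(out[c].to_numpy(float))
            q1, q3 = np.percentile(out[c].to_numpy(float), [25, 75])
            x, lam = power_transform(x)
            if np.ptp(x) == 0:
                # constant after transform: record passthrough scaling
                self.params[c] = {"lambda": lam, "mean": float(x[0]), "sd": 1.0,
                                  "lo": -np.inf, "hi": np.inf,
                                  "median": float(np.median(out[c]))}
                out[c] = x - x[0]
                continue
            z, mean, sd = zscore(x)
            iqr = q3 - q1
            self.params[c] = {"lambda": lam, "mean": mean, "sd": sd,
                              "lo": q1 - 1.5 * iqr, "hi": q3 + 1.5 * iqr,
                              "median": float(np.median(out[c]))}
            out[c] = z
        return out

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.columns is None:
            raise ParameterError("preprocessor not fitted")
        out = table.copy()
        for c in self.columns:
            p = self.params[c]
            x = out[c].to_numpy(float).copy()
            mask = (x < p["lo"]) | (x > p["hi"])
            x[mask] = p["median"]  # train fences and train median
            x, _ = power_transform(x, lmbda=p["lambda"])
            out[c] = (x - p["mean"]) / p["sd"]
        return out

    def to_dict(self) -> dict:
        return {"columns": self.columns, "params": self.params}
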