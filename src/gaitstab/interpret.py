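"""Model interpretation: partial dependence, Shapley attributions, and
shape estimators for the recovered dose-response curves.

Shapley values are estimated by permutation sampling against a fixed
background sample.  Along each sampled feature ordering, the marginal
contributions telescope from the background expectation to the model's
prediction at the explained point, so the additivity identity

    sum_j phi_j(x) = f(x) - E_background[f]

holds *exactly* for any number of sampled permutations; sampling only
affects how credit is shared among features.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError


def _predict_fn(model):
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(X)[:, 1]
    return model.predict


def partial_dependence(model, X: pd.DataFrame | np.ndarray, feature,
                       grid: np.ndarray | None = None,
                       n_grid: int = 30,
                       quantile_range: tuple[float, float] = (0.05, 0.95)
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Partial-dependence curve of one feature.

    For each grid value g, the feature column of every row of X is set to g
    and predictions are averaged.  The default grid spans the feature's
    5th-95th percentile range.
    """
    if isinstance(X, pd.DataFrame):
        if feature not in X.columns:
            raise ParameterError(f"feature {feature!r} not in X")
        j = list(X.columns).index(feature)
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, float)
        j = int(feature)
    if grid is None:
        lo, hi = np.quantile(Xv[:, j], quantile_range)
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, float)
    f = _predict_fn(model)
    n = len(Xv)
    stacked = np.repeat(Xv[None, :, :], len(grid), axis=0)
    for gi, g in enumerate(grid):
        stacked[gi, :, j] = g
    preds = f(stacked.reshape(-1, Xv.shape[1])).reshape(len(grid), n)
    return grid, preds.mean(axis=1)


def shap_values(model, X_background: pd.DataFrame | np.ndarray,
                X_explain: pd.DataFrame | np.ndarray, n_perms: int = 10,
                seed: int = 0) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley attributions.

    Returns ``(phi, expected_value)`` where ``phi`` is (n_explain, p) and
    ``expected_value`` is the mean background prediction; rows of ``phi``
    sum exactly to ``f(x) - expected_value``.
    """
    B = np.asarray(X_background.to_numpy(float)
                   if isinstance(X_background, pd.DataFrame) else X_background,
                   float)
    E = np.asarray(X_explain.to_numpy(float)
                   if isinstance(X_explain, pd.DataFrame) else X_explain, float)
    if B.ndim != 2 or len(B) == 0:
        raise ParameterError("background set must be a non-empty 2-D array")
    if E.ndim != 2 or E.shape[1] != B.shape[1]:
        raise ParameterError("explain set must match background feature count")
    rng = np.random.default_rng(seed)
    f = _predict_fn(model)
    n_bg, p = B.shape
    expected = float(np.mean(f(B)))
    phi = np.zeros((len(E), p))
    orders = [rng.permutation(p) for _ in range(n_perms)]
    for i, x in enumerate(E):
        acc = np.zeros(p)
        for order in orders:
            # stage s = background with the first s features of `order` set to x
            stages = np.repeat(B[None, :, :], p + 1, axis=0)
            for s in range(1, p + 1):
                stages[s:, :, order[s - 1]] = x[order[s - 1]]
            v = f(stages.reshape(-1, p)).reshape(p + 1, n_bg).mean(axis=1)
            acc[order] += np.diff(v)
        phi[i] = acc / n_perms
    return phi, expected


def shap_summary(model, X_background, X_explain, n_perms: int = 10,
                 seed: int = 0,
                 feature_names: list[str] | None = None) -> pd.DataFrame:
    """Global importance: mean |Shapley attribution| per feature, sorted."""
    phi, expected = shap_values(model, X_background, X_explain,
                                n_perms=n_perms, seed=seed)
    if feature_names is None:
        if isinstance(X_explain, pd.DataFrame):
            feature_names = list(X_explain.columns)
        else:
            feature_names = [f"f{i}" for i in range(phi.shape[1])]
    out = pd.DataFrame({"feature": feature_names,
                        "mean_abs_shap": np.mean(np.abs(phi), axis=0),
                        "mean_shap": np.mean(phi, axis=0)})
    out.attrs["expected_value"] = expected
    return out.sort_values("mean_abs_shap", ascending=False).reset_index(drop=True)


# --------------------------------------------------------------------------
# Curve-shape estimators for recovered dose-response structure
# --------------------------------------------------------------------------

def locate_breakpoint(grid: np.ndarray, curve: np.ndarray,
                      margin: int = 2) -> float:
    """Changepoint of a curve by continuous two-segment least squares.

    Every interior grid value is tried as the kink of a continuous
    piecewise-linear fit; the candidate minimizing the residual sum of
    squares is returned.
    """
    g = np.asarray(grid, float)
    y = np.asarray(curve, float)
    if len(g) < 2 * margin + 3:
        raise ParameterError("curve too short for breakpoint search")
    best_b, best_sse = g[margin], np.inf
    for b in g[margin:-margin]:
        design = np.column_stack([np.ones_like(g),
                                  np.minimum(g - b, 0.0),
                                  np.maximum(g - b, 0.0)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((design @ beta - y) ** 2))
        if sse < best_sse:
            best_b, best_sse = float(b), sse
    return best_b


def quadratic_coefficient(grid: np.ndarray, curve: np.ndarray) -> float:
    """Leading coefficient of a least-squares parabola through the curve
    (positive = U-shape)."""
    return float(np.polyfit(np.asarray(grid, float), np.asarray(curve, float), 2)[0])


def ushape_minimum(grid: np.ndarray, curve: np.ndarray) -> float:
    """Vertex location of the fitted parabola (the U-shape minimum)."""
    a, b, _ = np.polyfit(np.asarray(grid, float), np.asarray(curve, float), 2)
    if a <= 0:
        raise ParameterError("curve is not convex; no U-shape minimum")
    return float(-b / (2 * a))


def plateau_level(grid: np.ndarray, curve: np.ndarray,
                  tail_fraction: float = 0.25) -> float:
    """Saturation level of a ramp-then-plateau curve: the mean of the curve
    over the rightmost ``tail_fraction`` of the grid."""
    if not (0 < tail_fraction <= 1):
        raise ParameterError("tail_fraction must be in (0, 1]")
    y = np.asarray(curve, float)
    k = max(int(round(tail_fraction * len(y))), 1)
    return float(np.mean(y[-k:]))
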