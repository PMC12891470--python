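"""Sparse partial least squares discriminant analysis (sPLS-DA).

PLS2 (NIPALS) on standardized features against the centered one-hot class
indicator, with the X-weight vector soft-thresholded each iteration so that
exactly ``keepX[a]`` features carry nonzero weight in component ``a`` —
variable selection and classification in a single step.  Between
components, X is deflated on its loadings and Y on the component's
regression coefficients, which makes successive score vectors orthogonal
and the score/loading reconstruction of X exact.

Interpretation is by VIP (variable importance in projection): the
explained-Y-variance-weighted RMS of squared normalized weights, scaled so
that the mean squared VIP over all p features equals 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .experiment import roc_auc


@dataclass
class SplsdaModel:
    weights: np.ndarray      # p x A, unit-norm sparse X-weights
    x_loadings: np.ndarray   # p x A
    y_loadings: np.ndarray   # K x A
    scores: np.ndarray       # n x A training score vectors
    ss_y: np.ndarray         # per-component explained-Y-variance weight
    explained_x: np.ndarray  # per-component fraction of ||X||^2 explained
    class_means: dict        # class -> centroid in score space (length A)
    classes: list
    keepX: list[int] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    n_iter: list[int] = field(default_factory=list)

    @property
    def ncomp(self) -> int:
        return self.weights.shape[1]

    def transform(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Project (already standardized) data into the score space."""
        Xd = np.asarray(X.to_numpy(float) if isinstance(X, pd.DataFrame) else X,
                        float).copy()
        T = np.zeros((len(Xd), self.ncomp))
        for a in range(self.ncomp):
            t = Xd @ self.weights[:, a]
            T[:, a] = t
            Xd -= np.outer(t, self.x_loadings[:, a])
        return T


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold w so exactly ``keep`` entries stay nonzero."""
    p = len(w)
    if keep >= p:
        return w.copy()
    absw = np.abs(w)
    lam = np.sort(absw)[::-1][keep]  # (keep+1)-th largest magnitude
    return np.sign(w) * np.maximum(absw - lam, 0.0)


def fit_splsda(X: pd.DataFrame | np.ndarray, y, ncomp: int = 2,
               keepX: list[int] | None = None, max_iter: int = 500,
               tol: float = 1e-6, seed: int = 0) -> SplsdaModel:
    """Fit an sPLS-DA model on standardized X against class labels y.

    ``keepX`` gives the number of nonzero feature weights per component
    (default 4 per component, matching the sparse components used for
    trunk-acceleration discrimination).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xd = X.to_numpy(float).copy()
    else:
        Xd = np.asarray(X, float).copy()
        names = [f"f{i}" for i in range(Xd.shape[1])]
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist(), key=str)
    if len(classes) < 2:
        raise ParameterError("sPLS-DA needs at least two classes")
    n, p = Xd.shape
    keepX = list(keepX) if keepX is not None else [4] * ncomp
    if len(keepX) < ncomp:
        keepX = keepX + [keepX[-1]] * (ncomp - len(keepX))
    if any(k > p or k < 1 for k in keepX):
        raise ParameterError(f"keepX {keepX} out of range for p={p}")

    Y = np.zeros((n, len(classes)))
    for k, cls in enumerate(classes):
        Y[y == cls, k] = 1.0
    Y = Y - Y.mean(axis=0)
    x_total = float(np.sum(Xd**2))

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    C = np.zeros((Y.shape[1], ncomp))
    T = np.zeros((n, ncomp))
    ss_y = np.zeros(ncomp)
    exp_x = np.zeros(ncomp)
    iters = []
    for a in range(ncomp):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        w = np.zeros(p)
        it = 0
        for it in range(1, max_iter + 1):
            w_new = Xd.T @ u
            w_new = _soft_threshold_keep(w_new, keepX[a])
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                raise ParameterError(f"component {a + 1}: all weights thresholded away")
            w_new /= nrm
            t = Xd @ w_new
            tt = float(t @ t)
            if tt == 0:
                raise ParameterError(f"component {a + 1}: degenerate score vector")
            c = Y.T @ t / tt
            u = Y @ c / float(c @ c)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        iters.append(it)
        t = Xd @ w
        tt = float(t @ t)
        p_load = Xd.T @ t / tt
        c = Y.T @ t / tt
        W[:, a], P[:, a], C[:, a], T[:, a] = w, p_load, c, t
        ss_y[a] = float(c @ c) * tt
        exp_x[a] = float(np.sum(np.outer(t, p_load) ** 2)) / x_total
        Xd -= np.outer(t, p_load)
        Y -= np.outer(t, c)

    class_means = {cls: T[y == cls].mean(axis=0) for cls in classes}
    return SplsdaModel(weights=W, x_loadings=P, y_loadings=C, scores=T,
                       ss_y=ss_y, explained_x=exp_x, class_means=class_means,
                       classes=classes, keepX=keepX[:ncomp],
                       feature_names=names, n_iter=iters)


def decision_scores(model: SplsdaModel, X, positive_class,
                    up_to_component: int | None = None) -> np.ndarray:
    """Centroid-distance class score in cumulative score space: higher means
    closer to the positive-class centroid."""
    A = up_to_component or model.ncomp
    if not (1 <= A <= model.ncomp):
        raise ParameterError(f"up_to_component must be in [1, {model.ncomp}]")
    if positive_class not in model.classes:
        raise ParameterError(f"unknown class {positive_class!r}")
    T = model.transform(X)[:, :A]
    others = [c for c in model.classes if c != positive_class]
    mu_pos = model.class_means[positive_class][:A]
    d_pos = np.sum((T - mu_pos) ** 2, axis=1)
    d_neg = np.min([np.sum((T - model.class_means[c][:A]) ** 2, axis=1)
                    for c in others], axis=0)
    return d_neg - d_pos


def component_auc(model: SplsdaModel, X, y, positive_class,
                  up_to_component: int | None = None) -> list[float]:
    """AUC of the centroid-distance score using components 1..a, for each a."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ParameterError("component_auc needs both classes in y")
    A = up_to_component or model.ncomp
    y_bin = (y == positive_class).astype(int)
    return [roc_auc(decision_scores(model, X, positive_class, a), y_bin)
            for a in range(1, A + 1)]


def vip_scores(model: SplsdaModel) -> pd.DataFrame:
    """VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ).

    Weights are unit-norm per component, so mean(VIP^2) over the p features
    equals 1 exactly.
    """
    W2 = model.weights**2
    ss = model.ss_y
    p = W2.shape[0]
    vip = np.sqrt(p * (W2 @ ss) / ss.sum())
    return (pd.DataFrame({"feature": model.feature_names, "vip": vip})
            .sort_values("vip", ascending=False).reset_index(drop=True))
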