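"""Consensus feature selection: shadow-feature wrapper plus L1 path.

Two independent selectors run on the standardized feature table and only
features chosen by *both* are retained:

* :func:`boruta_select` — the Boruta shadow-feature algorithm: each
  iteration appends a shuffled copy of every feature, fits a random forest,
  and scores a "hit" for every real feature whose importance beats the best
  shadow importance; confirmation/rejection by two-sided binomial tests
  with Bonferroni correction.
* :func:`lasso_select` — the cross-validated L1 path (logistic deviance for
  binary labels, mean squared error for numeric targets); selected =
  features with nonzero coefficients at the chosen penalty.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ParameterError


@dataclass
class BorutaResult:
    confirmed: list[str]
    tentative: list[str]
    rejected: list[str]
    hits: dict[str, int]
    n_iter_run: int
    p_threshold: float


@dataclass
class LassoResult:
    selected: list[str]
    alphas: np.ndarray
    chosen_alpha: float
    coefficients: dict[str, float]
    rule: str = "lambda_min"


@dataclass
class SelectionReport:
    boruta: BorutaResult
    lasso: LassoResult
    consensus: list[str] = field(default_factory=list)
    empty_consensus: bool = False

    def to_dict(self) -> dict:
        return {
            "consensus": self.consensus,
            "empty_consensus": self.empty_consensus,
            "boruta": {"confirmed": self.boruta.confirmed,
                       "tentative": self.boruta.tentative,
                       "rejected": self.boruta.rejected,
                       "hits": self.boruta.hits,
                       "n_iter_run": self.boruta.n_iter_run},
            "lasso": {"selected": self.lasso.selected,
                      "chosen_log_lambda": float(np.log(self.lasso.chosen_alpha))
                      if self.lasso.chosen_alpha > 0 else None,
                      "rule": self.lasso.rule,
                      "coefficients": self.lasso.coefficients},
        }


def _is_classification(y: np.ndarray) -> bool:
    return len(np.unique(y)) == 2


def boruta_select(X: pd.DataFrame, y: np.ndarray | pd.Series, n_iter: int = 100,
                  alpha: float = 0.05, seed: int = 0,
                  n_estimators: int = 500) -> BorutaResult:
    """Boruta shadow-feature selection with a random-forest importance model.

    Each iteration shuffles a shadow copy of every feature column, fits a
    forest (sqrt-features splits) on [real | shadow], and credits a hit to
    every real feature whose Gini importance exceeds the maximum shadow
    importance.  After each iteration a feature is confirmed when its hit
    count is binomially improbable high (and rejected when improbably low)
    at ``alpha`` with Bonferroni correction over features.  Iteration stops
    early once nothing remains tentative.
    """
    if X.shape[1] < 2:
        raise ParameterError("boruta_select needs at least 2 features")
    if n_iter < 20:
        warnings.warn("n_iter < 20 gives unstable Boruta decisions", stacklevel=2)
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    names = list(X.columns)
    p = len(names)
    p_thr = alpha / p
    Xv = X.to_numpy(float)
    classif = _is_classification(y)
    forest_cls = RandomForestClassifier if classif else RandomForestRegressor

    hits = dict.fromkeys(names, 0)
    status = dict.fromkeys(names, "tentative")
    n_run = 0
    for it in range(1, n_iter + 1):
        n_run = it
        shadow = Xv.copy()
        for j in range(p):
            rng.shuffle(shadow[:, j])
        both = np.hstack([Xv, shadow])
        forest = forest_cls(n_estimators=n_estimators, max_features="sqrt",
                            random_state=int(rng.integers(2**31)), n_jobs=1)
        forest.fit(both, y)
        imp = forest.feature_importances_
        shadow_max = imp[p:].max()
        for j, name in enumerate(names):
            if imp[j] > shadow_max:
                hits[name] += 1
        for name in names:
            if status[name] != "tentative":
                continue
            k = hits[name]
            if stats.binom.sf(k - 1, it, 0.5) < p_thr:
                status[name] = "confirmed"
            elif stats.binom.cdf(k, it, 0.5) < p_thr:
                status[name] = "rejected"
        if all(s != "tentative" for s in status.values()):
            break
    return BorutaResult(
        confirmed=[n for n in names if status[n] == "confirmed"],
        tentative=[n for n in names if status[n] == "tentative"],
        rejected=[n for n in names if status[n] == "rejected"],
        hits=hits, n_iter_run=n_run, p_threshold=p_thr,
    )


def lasso_select(X: pd.DataFrame, y: np.ndarray | pd.Series, n_folds: int = 5,
                 rule: str = "lambda_min", seed: int = 0,
                 n_alphas: int = 50) -> LassoResult:
    """Cross-validated L1 selection.

    ``lambda_min`` takes the penalty minimizing mean CV loss; ``lambda_1se``
    the largest penalty within one standard error of that minimum.
    """
    if rule not in ("lambda_min", "lambda_1se"):
        raise ParameterError(f"unknown rule {rule!r}")
    y = np.asarray(y)
    names = list(X.columns)
    Xv = X.to_numpy(float)
    if _is_classification(y):
        y_bin = (y == np.unique(y)[1]).astype(int)
        Cs = np.logspace(-3, 2, n_alphas)
        cv = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
        model = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
            scoring="neg_log_loss", max_iter=5000, refit=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(Xv, y_bin)
        scores = next(iter(model.scores_.values()))  # folds x Cs (neg log-loss)
        mean_loss = -scores.mean(axis=0)
        se = scores.std(axis=0, ddof=1) / np.sqrt(n_folds)
        i_min = int(np.argmin(mean_loss))
        if rule == "lambda_1se":
            ok = mean_loss <= mean_loss[i_min] + se[i_min]
            i_sel = int(np.flatnonzero(ok)[0])  # Cs ascending: smallest C = largest penalty
        else:
            i_sel = i_min
        C_sel = Cs[i_sel]
        refit = LogisticRegressionCV(
            Cs=[C_sel], cv=cv, penalty="l1", solver="liblinear",
            scoring="neg_log_loss", max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            refit.fit(Xv, y_bin)
        coefs = refit.coef_[0]
        alphas = 1.0 / Cs
        chosen_alpha = 1.0 / C_sel
    else:
        cv = KFold(n_folds, shuffle=True, random_state=seed)
        model = LassoCV(n_alphas=n_alphas, cv=cv, random_state=seed, max_iter=50000)
        model.fit(Xv, y)
        alphas = model.alphas_
        mse = model.mse_path_.mean(axis=1)
        se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(n_folds)
        i_min = int(np.argmin(mse))
        if rule == "lambda_1se":
            ok = mse <= mse[i_min] + se[i_min]
            i_sel = int(np.flatnonzero(ok)[0])  # alphas descending: first ok = largest
        else:
            i_sel = i_min
        chosen_alpha = float(alphas[i_sel])
        from sklearn.linear_model import Lasso
        refit = Lasso(alpha=chosen_alpha, max_iter=50000)
        refit.fit(Xv, y)
        coefs = refit.coef_
    nz = np.abs(coefs) > 1e-10
    return LassoResult(
        selected=[n for n, keep in zip(names, nz) if keep],
        alphas=np.asarray(alphas), chosen_alpha=float(chosen_alpha),
        coefficients={n: float(c) for n, c in zip(names, coefs)}, rule=rule,
    )


def lasso_path_coefficients(X: np.ndarray, y: np.ndarray, alphas,
                            fit_intercept: bool = True) -> np.ndarray:
    """Linear L1 coefficient path at the given penalties (rows = alphas).

    Solves (1/2n)||y - Xb||^2 + alpha*||b||_1 to tight tolerance; on an
    orthonormal design (X'X = nI, no intercept) each solution equals the
    soft-thresholded least-squares estimate.
    """
    from sklearn.linear_model import Lasso
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    out = np.zeros((len(alphas), X.shape[1]))
    for i, a in enumerate(alphas):
        est = Lasso(alpha=float(a), fit_intercept=fit_intercept,
                    tol=1e-12, max_iter=200000)
        est.fit(X, y)
        out[i] = est.coef_
    return out


def consensus(a, b) -> tuple[list[str], bool]:
    """Exact intersection of two selected-feature sets.

    Returns ``(features, empty_flag)``; order follows ``a``.  Boruta
    "tentative" features are treated as not selected (strict reading of
    selection by both methods).
    """
    set_b = set(b)
    inter = [x for x in a if x in set_b]
    empty = len(inter) == 0
    if empty:
        warnings.warn("consensus feature set is empty", stacklevel=2)
    return inter, empty


def select_features(X: pd.DataFrame, y, seed: int = 0, n_iter: int = 100,
                    alpha: float = 0.05, rule: str = "lambda_min",
                    n_estimators: int = 500) -> SelectionReport:
    """Run Boruta and LASSO and intersect their selections."""
    bor = boruta_select(X, y, n_iter=n_iter, alpha=alpha, seed=seed,
                        n_estimators=n_estimators)
    las = lasso_select(X, y, seed=seed, rule=rule)
    inter, empty = consensus(bor.confirmed, las.selected)
    return SelectionReport(boruta=bor, lasso=las, consensus=inter,
                           empty_consensus=empty)
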