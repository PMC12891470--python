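"""Repeated stratified train/test experiments for Step 1 (classification)
and Step 2 (regression).

Protocol per repeat seed: stratified 80/20 split; normalization fit on the
training split only; augmentation of the training split only (and, inside
the 5-fold grid search, of each fold's training portion only, so augmented
instances are never shared across folds); refit of the winning
hyperparameters on the full augmented training split; evaluation on the
untouched test split.  Metrics are averaged over repeats.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (GradientBoostingRegressor, RandomForestClassifier,
                              RandomForestRegressor)
from sklearn.linear_model import ElasticNet, LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

from .augment import LABEL_COL, SYNTH_COL, augment_training_split
from .errors import ParameterError
from .prep import TablePreprocessor

log = logging.getLogger("gaitstab")

POSITIVE_CLASS = "PwS"


# --------------------------------------------------------------------------
# Metrics (binary scores thresholded at 0.5)
# --------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by pairwise ranking (ties credit 0.5)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ParameterError("roc_auc needs both classes present")
    diff = pos[:, None] - neg[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0))
                 / (len(pos) * len(neg)))


def brier(probs, labels) -> float:
    p = np.asarray(probs, float)
    y = np.asarray(labels).astype(int)
    return float(np.mean((p - y) ** 2))


def confusion_metrics(probs, labels, threshold: float = 0.5) -> dict[str, float]:
    """Sensitivity, specificity and F1 at the given probability threshold."""
    p = np.asarray(probs, float)
    y = np.asarray(labels).astype(int)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return {"sensitivity": sens, "specificity": spec, "f1": f1}


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    y, yh = np.asarray(y_true, float), np.asarray(y_pred, float)
    resid = y - yh
    mse = float(np.mean(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return {"r2": 1.0 - np.sum(resid**2) / sst if sst > 0 else float("nan"),
            "rmse": float(np.sqrt(mse)), "mae": float(np.mean(np.abs(resid))),
            "mse": mse}


def odds_ratios(model: LogisticRegression, feature_names: list[str]) -> dict[str, float]:
    """Per-feature odds ratio exp(beta) of a fitted logistic model on
    standardized features."""
    if not hasattr(model, "coef_"):
        raise ParameterError("model is not a fitted logistic regression")
    return {n: float(np.exp(c)) for n, c in zip(feature_names, model.coef_[0])}


# --------------------------------------------------------------------------
# Experiment plans
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    name: str
    factory: Callable[[int], Any]  # seed -> unfitted estimator
    grid: dict[str, list]

    def param_combos(self):
        keys = list(self.grid)
        for vals in itertools.product(*(self.grid[k] for k in keys)):
            yield dict(zip(keys, vals))


@dataclass
class ExperimentPlan:
    models: list[ModelSpec]
    augmenters: list[tuple[str, str | None]] = field(
        default_factory=lambda: [("none", None)])
    n_repeats: int = 50
    test_size: float = 0.2
    inner_folds: int = 5
    base_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")
        for m in self.models:
            if not m.grid or any(len(v) == 0 for v in m.grid.values()):
                raise ParameterError(f"model {m.name}: empty hyperparameter grid")


def _xgb_classifier(seed: int, **kw):
    from xgboost import XGBClassifier
    return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss",
                         verbosity=0, **kw)


def default_classification_plan(n_repeats: int = 50, compact: bool = False,
                                augmenters: list | None = None,
                                base_seed: int = 42) -> ExperimentPlan:
    """Six classifiers (two glass-box, four black-box) with grid-search
    hyperparameters; ``compact=True`` keeps two representative models and
    minimal grids for quick runs."""
    if compact:
        models = [
            ModelSpec("logistic", lambda s: LogisticRegression(max_iter=2000),
                      {"C": [0.1, 1.0]}),
            ModelSpec("svc", lambda s: SVC(probability=True, random_state=s),
                      {"C": [1.0, 10.0]}),
            ModelSpec("random_forest",
                      lambda s: RandomForestClassifier(random_state=s, n_jobs=1),
                      {"n_estimators": [200], "max_depth": [None]}),
        ]
    else:
        models = [
            ModelSpec("logistic", lambda s: LogisticRegression(max_iter=2000),
                      {"C": [0.01, 0.1, 1.0, 10.0]}),
            ModelSpec("decision_tree",
                      lambda s: DecisionTreeClassifier(random_state=s),
                      {"max_depth": [3, 5, None], "min_samples_leaf": [1, 5]}),
            ModelSpec("svc", lambda s: SVC(probability=True, random_state=s),
                      {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]}),
            ModelSpec("xgboost", _xgb_classifier,
                      {"n_estimators": [100, 300], "max_depth": [3, 6],
                       "learning_rate": [0.1]}),
            ModelSpec("random_forest",
                      lambda s: RandomForestClassifier(random_state=s, n_jobs=1),
                      {"n_estimators": [200, 500], "max_depth": [None, 5, 10]}),
            ModelSpec("knn", lambda s: KNeighborsClassifier(),
                      {"n_neighbors": [3, 5, 7, 9]}),
        ]
    aug = augmenters if augmenters is not None else [("none", None),
                                                     ("smote", "balance100")]
    return ExperimentPlan(models=models, augmenters=aug, n_repeats=n_repeats,
                          base_seed=base_seed)


def default_regression_plan(n_repeats: int = 50, compact: bool = False,
                            base_seed: int = 42) -> ExperimentPlan:
    """Three linear and three nonlinear regressors."""
    if compact:
        models = [
            ModelSpec("linear", lambda s: LinearRegression(), {"fit_intercept": [True]}),
            ModelSpec("random_forest",
                      lambda s: RandomForestRegressor(random_state=s, n_jobs=1),
                      {"n_estimators": [200], "max_depth": [None]}),
        ]
    else:
        models = [
            ModelSpec("linear", lambda s: LinearRegression(), {"fit_intercept": [True]}),
            ModelSpec("svr", lambda s: SVR(),
                      {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]}),
            ModelSpec("elastic_net", lambda s: ElasticNet(max_iter=50000),
                      {"alpha": list(np.logspace(-3, 0, 4)),
                       "l1_ratio": [0.2, 0.5, 0.8]}),
            ModelSpec("random_forest",
                      lambda s: RandomForestRegressor(random_state=s, n_jobs=1),
                      {"n_estimators": [200, 500], "max_depth": [None, 5, 10]}),
            ModelSpec("gboost", lambda s: GradientBoostingRegressor(random_state=s),
                      {"n_estimators": [100, 300], "max_depth": [3]}),
            ModelSpec("knn", lambda s: KNeighborsRegressor(),
                      {"n_neighbors": [3, 5, 7, 9]}),
        ]
    return ExperimentPlan(models=models, n_repeats=n_repeats, base_seed=base_seed)


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Per-repeat raw metrics plus fitted artifacts of the last repeat."""

    task: str
    raw: pd.DataFrame  # one row per model x augmenter x repeat
    fitted_models: dict[tuple[str, str], Any] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    test_tables: dict[int, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        metrics = [c for c in self.raw.columns
                   if c not in ("model", "augmenter", "target_size", "repeat", "seed",
                                "best_params")]
        g = self.raw.groupby(["model", "augmenter", "target_size"])[metrics]
        out = g.agg(["mean", "std"])
        out.columns = [f"{m}_{s}" for m, s in out.columns]
        return out.reset_index()

    def best(self, metric: str = "auc", maximize: bool = True) -> pd.Series:
        s = self.summary()
        col = f"{metric}_mean"
        idx = s[col].idxmax() if maximize else s[col].idxmin()
        return s.loc[idx]


# --------------------------------------------------------------------------
# Runners
# --------------------------------------------------------------------------

def _grid_search_classification(train: pd.DataFrame, feats: list[str],
                                spec: ModelSpec, method: str, target,
                                folds: int, seed: int) -> dict:
    """Inner CV: folds are drawn over *real* rows; each fold's training
    portion is augmented independently so synthetic rows never cross folds."""
    combos = list(spec.param_combos())
    if len(combos) == 1:
        return combos[0]
    y = (train[LABEL_COL] == POSITIVE_CLASS).astype(int).to_numpy()
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    fold_data = []
    for k, (tr, va) in enumerate(skf.split(train[feats], y)):
        fold_train = train.iloc[tr]
        if method != "none":
            fold_train = augment_training_split(fold_train, method, target,
                                                seed=seed + 1000 * (k + 1),
                                                feature_cols=feats)
        Xt = fold_train[feats].to_numpy(float)
        yt = (fold_train[LABEL_COL] == POSITIVE_CLASS).astype(int).to_numpy()
        fold_data.append((Xt, yt, train.iloc[va][feats].to_numpy(float), y[va]))
    best, best_score = combos[0], -np.inf
    for params in combos:
        scores = []
        for Xt, yt, Xv, yv in fold_data:
            if len(np.unique(yv)) < 2:
                continue
            est = spec.factory(seed)
            est.set_params(**params)
            est.fit(Xt, yt)
            scores.append(roc_auc(_positive_probs(est, Xv), yv))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best, best_score = params, score
    return best


def _positive_probs(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    from scipy.special import expit
    return expit(est.decision_function(X))


def run_classification(table: pd.DataFrame, plan: ExperimentPlan,
                       label_col: str = LABEL_COL,
                       feature_cols: list[str] | None = None,
                       preprocess: bool = True) -> ExperimentReport:
    """Step-1 experiment: discriminate the two groups from the feature table."""
    if label_col not in table.columns:
        raise ParameterError(f"label column {label_col!r} missing")
    feats = feature_cols or [c for c in table.columns
                             if c not in (label_col, "subject_id")
                             and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    fitted: dict[tuple[str, str], Any] = {}
    test_tables: dict[int, pd.DataFrame] = {}
    for rep in range(plan.n_repeats):
        seed = plan.base_seed + rep
        log.info("classification repeat %d (seed %d)", rep, seed)
        y_all = table[label_col]
        train, test = train_test_split(table, test_size=plan.test_size,
                                       stratify=y_all, random_state=seed)
        train_t, test_t = train.copy(), test.copy()
        if preprocess:
            prep = TablePreprocessor(columns=feats)
            train_t[feats] = prep.fit_transform(train[feats])[feats]
            test_t[feats] = prep.transform(test[feats])[feats]
        y_test = (test_t[label_col] == POSITIVE_CLASS).astype(int).to_numpy()
        test_tables[rep] = test_t
        for method, target in plan.augmenters:
            aug_name = method if target is None else f"{method}_{target}"
            if method != "none":
                train_aug = augment_training_split(train_t, method, target,
                                                   seed=seed, feature_cols=feats)
            else:
                train_aug = train_t.copy()
                train_aug[SYNTH_COL] = False
            Xa = train_aug[feats].to_numpy(float)
            ya = (train_aug[label_col] == POSITIVE_CLASS).astype(int).to_numpy()
            for spec in plan.models:
                best = _grid_search_classification(
                    train_t, feats, spec, method, target, plan.inner_folds, seed)
                est = spec.factory(seed)
                est.set_params(**best)
                est.fit(Xa, ya)
                probs = _positive_probs(est, test_t[feats].to_numpy(float))
                row = {"model": spec.name, "augmenter": aug_name,
                       "target_size": str(target), "repeat": rep, "seed": seed,
                       "auc": roc_auc(probs, y_test),
                       "brier": brier(probs, y_test),
                       "best_params": repr(best)}
                row.update(confusion_metrics(probs, y_test))
                rows.append(row)
                fitted[(spec.name, aug_name)] = est
    return ExperimentReport(task="classification", raw=pd.DataFrame(rows),
                            fitted_models=fitted, feature_names=feats,
                            test_tables=test_tables)


def _grid_search_regression(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                            folds: int, seed: int) -> dict:
    combos = list(spec.param_combos())
    if len(combos) == 1:
        return combos[0]
    kf = KFold(folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best, best_score = combos[0], np.inf
    for params in combos:
        errs = []
        for tr, va in splits:
            est = spec.factory(seed)
            est.set_params(**params)
            est.fit(X[tr], y[tr])
            errs.append(np.mean((est.predict(X[va]) - y[va]) ** 2))
        score = float(np.mean(errs))
        if score < best_score:
            best, best_score = params, score
    return best


def run_regression(table: pd.DataFrame, plan: ExperimentPlan, target: str,
                   feature_cols: list[str] | None = None,
                   preprocess: bool = True) -> ExperimentReport:
    """Step-2 experiment: predict an uneven-surface quantity from
    even-surface predictors."""
    if target not in table.columns:
        raise ParameterError(f"target column {target!r} missing")
    feats = feature_cols or [c for c in table.columns
                             if c not in (target, "subject_id")
                             and not c.startswith("uneven_")
                             and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    fitted: dict[tuple[str, str], Any] = {}
    test_tables: dict[int, pd.DataFrame] = {}
    for rep in range(plan.n_repeats):
        seed = plan.base_seed + rep
        log.info("regression repeat %d (seed %d, target %s)", rep, seed, target)
        train, test = train_test_split(table, test_size=plan.test_size,
                                       random_state=seed)
        train_t, test_t = train.copy(), test.copy()
        if preprocess:
            prep = TablePreprocessor(columns=feats)
            train_t[feats] = prep.fit_transform(train[feats])[feats]
            test_t[feats] = prep.transform(test[feats])[feats]
        test_tables[rep] = test_t
        Xtr = train_t[feats].to_numpy(float)
        ytr = train_t[target].to_numpy(float)
        Xte = test_t[feats].to_numpy(float)
        yte = test_t[target].to_numpy(float)
        for spec in plan.models:
            best = _grid_search_regression(Xtr, ytr, spec, plan.inner_folds, seed)
            est = spec.factory(seed)
            est.set_params(**best)
            est.fit(Xtr, ytr)
            row = {"model": spec.name, "augmenter": "none", "target_size": "None",
                   "repeat": rep, "seed": seed, "best_params": repr(best)}
            row.update(regression_metrics(yte, est.predict(Xte)))
            rows.append(row)
            fitted[(spec.name, "none")] = est
    return ExperimentReport(task=f"regression:{target}", raw=pd.DataFrame(rows),
                            fitted_models=fitted, feature_names=feats,
                            test_tables=test_tables)
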