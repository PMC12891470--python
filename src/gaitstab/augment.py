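"""Training-split augmentation: SMOTE and lightweight tabular GANs.

All augmenters operate in the *standardized* feature space and see only the
training split — synthetic rows carry an ``is_synthetic`` flag and are used
solely for model fitting, never for evaluation.

Three methods are provided behind one contract:

* ``smote`` — synthetic minority oversampling: each synthetic row is a
  random convex combination of a minority row and one of its k nearest
  minority neighbors.
* ``gan`` — a small fully-connected generator/discriminator pair per class
  (one hidden layer each, Adam, non-saturating loss), trained on the class
  rows, with a per-feature affine output calibration to the training
  marginal mean/SD.
* ``ctgan`` — the same adversarial pair trained once across classes with a
  one-hot class condition appended to both networks; sampling conditions on
  the requested class.  This is a deliberately lightweight conditional
  generator: the pipeline's claims concern the augmentation harness, not a
  specific deep architecture.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import ParameterError

LABEL_COL = "group"
SYNTH_COL = "is_synthetic"


# --------------------------------------------------------------------------
# SMOTE
# --------------------------------------------------------------------------

def smote(X_minority: np.ndarray, n_synth: int, k: int = 5,
          seed: int = 0) -> np.ndarray:
    """Generate ``n_synth`` synthetic rows by neighbor interpolation.

    Each row is ``x_i + u * (x_nn - x_i)`` with ``u ~ Uniform(0, 1)`` and
    ``x_nn`` one of the k nearest neighbors (Euclidean) of ``x_i`` within
    the minority set, so every synthetic point lies on a segment between
    two minority rows.
    """
    X = np.atleast_2d(np.asarray(X_minority, float))
    n = len(X)
    if n < 2:
        raise ParameterError("SMOTE needs at least 2 minority rows")
    if n_synth < 0:
        raise ParameterError("n_synth must be non-negative")
    if n_synth == 0:
        return np.empty((0, X.shape[1]))
    if n <= k:
        warnings.warn(f"minority count {n} <= k={k}; reducing k to {n - 1}",
                      stacklevel=2)
        k = n - 1
    rng = np.random.default_rng(seed)
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1)[:, :k]
    base = rng.integers(0, n, size=n_synth)
    pick = rng.integers(0, k, size=n_synth)
    neighbor = nn_idx[base, pick]
    u = rng.uniform(0.0, 1.0, size=(n_synth, 1))
    return X[base] + u * (X[neighbor] - X[base])


# --------------------------------------------------------------------------
# Lightweight adversarial tabular generator (numpy, manual backprop)
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _lrelu(x, a=0.2):
    return np.where(x > 0, x, a * x)


def _lrelu_grad(x, a=0.2):
    return np.where(x > 0, 1.0, a)


@dataclass
class TabularGenerator:
    """Pluggable sample-by-class contract over a trained adversarial pair."""

    kind: str
    feature_names: list[str]
    classes: list[Any]
    latent_dim: int
    _gen_params: dict[Any, list[np.ndarray]] = field(default_factory=dict, repr=False)
    _calibration: dict[Any, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = \
        field(default_factory=dict, repr=False)
    _seed: int = 0

    def _forward_g(self, params: list[np.ndarray], z: np.ndarray) -> np.ndarray:
        W1, b1, W2, b2 = params
        return np.tanh(z @ W1 + b1) @ W2 + b2

    def sample(self, n: int, cls: Any, seed: int | None = None) -> np.ndarray:
        """Draw ``n`` synthetic rows of class ``cls`` (standardized space)."""
        if cls not in self._gen_params:
            raise ParameterError(f"unknown class {cls!r}; trained on {self.classes}")
        if n < 0:
            raise ParameterError("n must be non-negative")
        rng = np.random.default_rng(self._seed + 7919 if seed is None else seed)
        z = rng.standard_normal((n, self.latent_dim))
        raw = self._forward_g(self._gen_params[cls], z)
        mu_g, sd_g, mu_t, sd_t = self._calibration[cls]
        return (raw - mu_g) / sd_g * sd_t + mu_t

    def marginal_quality(self, X_train: np.ndarray, cls: Any,
                         n_check: int = 500) -> dict[str, np.ndarray]:
        """Per-feature |mean diff| and |SD diff| in units of the training SD."""
        S = self.sample(n_check, cls, seed=self._seed + 104729)
        mu_t, sd_t = X_train.mean(axis=0), X_train.std(axis=0)
        sd_t = np.where(sd_t == 0, 1.0, sd_t)
        return {"mean_gap_sd": np.abs(S.mean(axis=0) - mu_t) / sd_t,
                "sd_gap_sd": np.abs(S.std(axis=0) - X_train.std(axis=0)) / sd_t}


def _train_adversarial(X: np.ndarray, cond: np.ndarray | None, latent_dim: int,
                       hidden: int, epochs: int, batch: int, lr: float,
                       rng: np.random.Generator) -> list[np.ndarray]:
    """Train one generator/discriminator pair; returns generator parameters.

    ``cond`` (n x c one-hot) is appended to the generator input and the
    discriminator input when given.
    """
    n, p = X.shape
    c = 0 if cond is None else cond.shape[1]
    sc = 0.1
    W1 = sc * rng.standard_normal((latent_dim + c, hidden)); b1 = np.zeros(hidden)
    W2 = sc * rng.standard_normal((hidden, p)); b2 = X.mean(axis=0).copy()
    U1 = sc * rng.standard_normal((p + c, hidden)); c1 = np.zeros(hidden)
    U2 = sc * rng.standard_normal((hidden, 1)); c2 = np.zeros(1)
    opt_g = _Adam([W1, b1, W2, b2], lr=lr)
    opt_d = _Adam([U1, c1, U2, c2], lr=lr)

    def d_forward(xin):
        h_pre = xin @ U1 + c1
        h = _lrelu(h_pre)
        logit = (h @ U2 + c2)[:, 0]
        return h_pre, h, logit

    def d_backward(xin, h_pre, h, dlogit):
        # returns grads for D params and gradient wrt xin
        gU2 = h.T @ dlogit[:, None]
        gc2 = dlogit.sum(keepdims=True)
        dh = dlogit[:, None] @ U2.T
        dh_pre = dh * _lrelu_grad(h_pre)
        gU1 = xin.T @ dh_pre
        gc1 = dh_pre.sum(axis=0)
        dxin = dh_pre @ U1.T
        return [gU1, gc1, gU2, gc2], dxin

    steps_per_epoch = max(n // batch, 1)
    for _ in range(epochs):
        for _ in range(steps_per_epoch):
            idx = rng.integers(0, n, size=min(batch, n))
            x_real = X[idx]
            cnd = None if cond is None else cond[idx]
            z = rng.standard_normal((len(idx), latent_dim))
            g_in = z if cnd is None else np.hstack([z, cnd])
            h1_pre = g_in @ W1 + b1
            h1 = np.tanh(h1_pre)
            x_fake = h1 @ W2 + b2

            # --- discriminator step ---
            d_in_real = x_real if cnd is None else np.hstack([x_real, cnd])
            d_in_fake = x_fake if cnd is None else np.hstack([x_fake, cnd])
            hr_pre, hr, l_real = d_forward(d_in_real)
            hf_pre, hf, l_fake = d_forward(d_in_fake)
            if not (np.all(np.isfinite(l_real)) and np.all(np.isfinite(l_fake))):
                raise ParameterError(
                    "adversarial training diverged (non-finite discriminator logits)")
            m = len(idx)
            d_real = (1.0 / (1 + np.exp(-l_real)) - 1.0) / m  # target 1
            d_fake = (1.0 / (1 + np.exp(-l_fake)) - 0.0) / m  # target 0
            gr, _ = d_backward(d_in_real, hr_pre, hr, d_real)
            gf, _ = d_backward(d_in_fake, hf_pre, hf, d_fake)
            opt_d.step([a + b for a, b in zip(gr, gf)])

            # --- generator step (non-saturating) ---
            hf_pre, hf, l_fake = d_forward(d_in_fake)
            dlogit = (1.0 / (1 + np.exp(-l_fake)) - 1.0) / m  # target 1
            _, dxin = d_backward(d_in_fake, hf_pre, hf, dlogit)
            dx_fake = dxin[:, :p]  # condition columns carry no generator grad
            gW2 = h1.T @ dx_fake
            gb2 = dx_fake.sum(axis=0)
            dh1 = dx_fake @ W2.T
            dh1_pre = dh1 * (1 - h1**2)
            gW1 = g_in.T @ dh1_pre
            gb1 = dh1_pre.sum(axis=0)
            opt_g.step([gW1, gb1, gW2, gb2])
    return [W1, b1, W2, b2]


def fit_tabular_generator(X_train: pd.DataFrame | np.ndarray,
                          labels: np.ndarray | pd.Series, kind: str = "gan",
                          seed: int = 0, latent_dim: int = 8, hidden: int = 32,
                          epochs: int = 200, batch: int = 32, lr: float = 1e-3,
                          quality_gate_sd: float = 0.5) -> TabularGenerator:
    """Fit an adversarial tabular generator on the (standardized) training
    split.

    ``kind='gan'`` trains an independent pair per class; ``kind='ctgan'``
    trains a single class-conditional pair.  Generator outputs receive a
    per-feature affine calibration to the class's training marginal mean/SD
    (computed from a large generated sample); a warning is emitted if a
    check sample still misses any marginal by more than ``quality_gate_sd``
    training SDs.
    """
    if kind not in ("gan", "ctgan"):
        raise ParameterError(f"kind must be 'gan' or 'ctgan', got {kind!r}")
    if isinstance(X_train, pd.DataFrame):
        names = list(X_train.columns)
        X = X_train.to_numpy(float)
    else:
        X = np.asarray(X_train, float)
        names = [f"f{i}" for i in range(X.shape[1])]
    labels = np.asarray(labels)
    classes = list(pd.unique(labels))
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ParameterError(f"class {cls!r} has fewer than 2 rows")
    rng = np.random.default_rng(seed)
    gen = TabularGenerator(kind=kind, feature_names=names, classes=classes,
                           latent_dim=latent_dim, _seed=seed)
    if kind == "gan":
        for cls in classes:
            Xc = X[labels == cls]
            params = _train_adversarial(Xc, None, latent_dim, hidden, epochs,
                                        batch, lr, rng)
            gen._gen_params[cls] = params
            _calibrate(gen, cls, Xc, rng)
    else:
        onehot = np.zeros((len(X), len(classes)))
        for i, cls in enumerate(classes):
            onehot[labels == cls, i] = 1.0
        params = _train_adversarial(X, onehot, latent_dim, hidden, epochs,
                                    batch, lr, rng)
        for i, cls in enumerate(classes):
            # conditional sampling = shared weights with the class bit folded in:
            # z @ W1 + onehot_c @ W1_cond + b1  ==  z @ W1z + (b1 + W1[latent+i])
            W1, b1, W2, b2 = params
            W1z = W1[:latent_dim]
            b1c = b1 + W1[latent_dim + i]
            gen._gen_params[cls] = [W1z, b1c, W2, b2]
            _calibrate(gen, cls, X[labels == cls], rng)
    for cls in classes:
        q = gen.marginal_quality(X[labels == cls], cls)
        worst = max(q["mean_gap_sd"].max(), q["sd_gap_sd"].max())
        if worst > quality_gate_sd:
            warnings.warn(
                f"{kind} marginal quality gate: class {cls!r} worst gap "
                f"{worst:.2f} SD exceeds {quality_gate_sd}", stacklevel=2)
    return gen


def _calibrate(gen: TabularGenerator, cls, X_cls: np.ndarray,
               rng: np.random.Generator) -> None:
    z = rng.standard_normal((2000, gen.latent_dim))
    raw = gen._forward_g(gen._gen_params[cls], z)
    mu_g, sd_g = raw.mean(axis=0), raw.std(axis=0)
    sd_g = np.where(sd_g < 1e-8, 1.0, sd_g)
    gen._calibration[cls] = (mu_g, sd_g, X_cls.mean(axis=0), X_cls.std(axis=0))


# --------------------------------------------------------------------------
# Split-level augmentation
# --------------------------------------------------------------------------

def _allocate(counts: dict[Any, int], target: str | int) -> dict[Any, int]:
    """How many synthetic rows per class for a target-size policy."""
    classes = sorted(counts, key=counts.get)  # minority first
    minority, majority = classes[0], classes[-1]
    if target == "balance100":
        return {minority: max(0, 100 - counts[minority]), majority: 0}
    if isinstance(target, str) and target.startswith("N"):
        total = int(target[1:])
    elif isinstance(target, int):
        total = target
    else:
        raise ParameterError(f"unknown target size {target!r}")
    gap = counts[majority] - counts[minority]
    to_minority = min(total, gap)
    rest = total - to_minority
    alloc = {minority: to_minority + rest // 2 + rest % 2,
             majority: rest // 2}
    return alloc


def augment_training_split(train: pd.DataFrame, method: str = "smote",
                           target: str | int = "balance100", seed: int = 0,
                           label_col: str = LABEL_COL,
                           feature_cols: list[str] | None = None,
                           generator_kwargs: dict | None = None) -> pd.DataFrame:
    """Return the training split plus flagged synthetic rows.

    ``method`` is one of ``none``/``smote``/``gan``/``ctgan``; ``target`` is
    ``balance100`` (grow the minority class to 100), ``N200``/``N1000`` (add
    that many synthetic rows in total, equalizing classes first) or an
    integer total.  Real rows pass through bit-for-bit with
    ``is_synthetic=False``; the augmenter is fit on the given split only.
    """
    if label_col not in train.columns:
        raise ParameterError(f"label column {label_col!r} missing")
    out = train.copy()
    out[SYNTH_COL] = False
    if method == "none":
        return out
    feats = feature_cols or [c for c in train.columns
                             if c not in (label_col, "subject_id", SYNTH_COL)
                             and pd.api.types.is_numeric_dtype(train[c])]
    counts = train[label_col].value_counts().to_dict()
    if len(counts) != 2:
        raise ParameterError("augmentation expects a binary label")
    alloc = _allocate(counts, target)

    synth_frames = []
    if method == "smote":
        for i, (cls, n_syn) in enumerate(sorted(alloc.items(), key=lambda kv: str(kv[0]))):
            if n_syn <= 0:
                continue
            Xc = train.loc[train[label_col] == cls, feats].to_numpy(float)
            rows = smote(Xc, n_synth=n_syn, seed=seed + i)
            synth_frames.append(_as_frame(rows, feats, cls, label_col))
    elif method in ("gan", "ctgan"):
        gen = fit_tabular_generator(train[feats], train[label_col], kind=method,
                                    seed=seed, **(generator_kwargs or {}))
        for i, (cls, n_syn) in enumerate(sorted(alloc.items(), key=lambda kv: str(kv[0]))):
            if n_syn <= 0:
                continue
            rows = gen.sample(n_syn, cls, seed=seed + 31 * (i + 1))
            synth_frames.append(_as_frame(rows, feats, cls, label_col))
    else:
        raise ParameterError(f"unknown augmentation method {method!r}")
    if synth_frames:
        out = pd.concat([out, *synth_frames], ignore_index=True)
    return out


def _as_frame(rows: np.ndarray, feats: list[str], cls, label_col: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=feats)
    df[label_col] = cls
    df[SYNTH_COL] = True
    return df
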