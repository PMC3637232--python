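"""Mass / normal-tissue classifiers: Rprop-trained MLP and RBF-kernel SVM.

Two classifier families operate on the ICA coefficient vectors:

* a single-hidden-layer perceptron with logistic activations and one sigmoid
  output (targets mass=1, normal=0), trained by batch resilient
  backpropagation (Rprop with weight backtracking) on the sum-of-squares
  error, with validation-based early stopping and model selection over a
  hidden-layer grid with random restarts;
* a soft-margin SVM with Gaussian kernel ``K(x, y) = exp(-gamma ||x-y||^2)``,
  tuned by exhaustive validation-set search over base-2 exponent grids for
  gamma and the penalty C.

Success rates are reported at the intermediate decision threshold: 0.5 on
the sigmoid output, 0 on the SVM decision value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .ica_features import FeatureMatrix

DEFAULT_H_GRID: tuple[int, ...] = tuple(range(50, 651, 50))
DEFAULT_GAMMA_EXPS: np.ndarray = np.arange(-5.0, 20.0 + 1e-9, 0.5)
DEFAULT_C_EXPS: np.ndarray = np.arange(-5.0, 10.0 + 1e-9, 0.5)


@dataclass(frozen=True)
class RpropConfig:
    """Rprop step-adaptation constants (the original algorithm's defaults)."""

    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0
    max_epochs: int = 1000
    patience: int = 50
    restarts: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.eta_minus < 1 < self.eta_plus):
            raise ValueError("require 0 < eta_minus < 1 < eta_plus")
        if not (self.delta_min < self.delta0 < self.delta_max):
            raise ValueError("require delta_min < delta0 < delta_max")


@dataclass(frozen=True)
class LearningSplit:
    """Disjoint train / validation / test index sets."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        sets = [set(self.train.tolist()), set(self.val.tolist()),
                set(self.test.tolist())]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("split partitions overlap")

    @classmethod
    def from_test_mask(cls, y: np.ndarray, test_mask: np.ndarray,
                       val_fraction: float = 0.2,
                       seed: int = 0) -> "LearningSplit":
        """Fixed test set; the remaining learning set is split train/val
        (stratified by label)."""
        idx = np.arange(len(y))
        learn = idx[~test_mask]
        test = idx[test_mask]
        train, val = train_test_split(
            learn, test_size=val_fraction, random_state=seed,
            stratify=y[learn] if len(np.unique(y[learn])) > 1 else None)
        return cls(train=np.sort(train), val=np.sort(val), test=np.sort(test))

    @classmethod
    def random(cls, y: np.ndarray, test_fraction: float = 0.1,
               val_fraction: float = 0.2, seed: int = 0,
               stratify: np.ndarray | None = None) -> "LearningSplit":
        """Random learning/test split (default ~90/10), then train/val."""
        idx = np.arange(len(y))
        strat = stratify if stratify is not None else y
        learn, test = train_test_split(idx, test_size=test_fraction,
                                       random_state=seed, stratify=strat)
        mask = np.zeros(len(y), dtype=bool)
        mask[test] = True
        return cls.from_test_mask(y, mask, val_fraction=val_fraction, seed=seed)


# ---------------------------------------------------------------------------
# Rprop core (shared by the MLP trainer and usable on any batch gradient)
# ---------------------------------------------------------------------------

class RpropState:
    """Per-weight adaptive steps for batch Rprop with backtracking.

    On sign agreement of successive gradients the step grows by ``eta_plus``
    (capped at ``delta_max``); on disagreement it shrinks by ``eta_minus``
    (floored at ``delta_min``), the previous weight step is reverted, and the
    stored gradient is zeroed so the next update cannot flip again.
    """

    def __init__(self, n: int, cfg: RpropConfig):
        self.cfg = cfg
        self.delta = np.full(n, cfg.delta0)
        self.prev_grad = np.zeros(n)
        self.prev_step = np.zeros(n)

    def step(self, grad: np.ndarray) -> np.ndarray:
        """Return the weight increment for this epoch's batch gradient."""
        cfg = self.cfg
        sign = np.sign(grad * self.prev_grad)
        self.delta = np.where(sign > 0,
                              np.minimum(self.delta * cfg.eta_plus, cfg.delta_max),
                              np.where(sign < 0,
                                       np.maximum(self.delta * cfg.eta_minus,
                                                  cfg.delta_min),
                                       self.delta))
        step = np.where(sign < 0, -self.prev_step, -np.sign(grad) * self.delta)
        self.prev_grad = np.where(sign < 0, 0.0, grad)
        self.prev_step = step
        return step


def rprop_minimize(grad_fn: Callable[[np.ndarray], np.ndarray],
                   w0: np.ndarray, cfg: RpropConfig | None = None,
                   max_epochs: int | None = None) -> np.ndarray:
    """Minimize a differentiable function by batch Rprop on its gradient."""
    cfg = cfg or RpropConfig()
    w = np.asarray(w0, dtype=float).copy()
    state = RpropState(w.size, cfg)
    for _ in range(max_epochs if max_epochs is not None else cfg.max_epochs):
        w = w + state.step(grad_fn(w))
    return w


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class MLPModel:
    """q -> H -> 1 perceptron with logistic activations throughout."""

    W1: np.ndarray  # (H, n_in)
    b1: np.ndarray  # (H,)
    w2: np.ndarray  # (H,)
    b2: float
    H: int = field(init=False)
    n_in: int = field(init=False)

    def __post_init__(self) -> None:
        self.H, self.n_in = self.W1.shape

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid outputs in (0, 1); higher = more mass-like."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_in:
            raise ValueError("feature dimension does not match model input")
        h = _sigmoid(X @ self.W1.T + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)


def _init_mlp(n_in: int, H: int, rng: np.random.Generator) -> MLPModel:
    return MLPModel(W1=rng.normal(0.0, 1.0 / math.sqrt(n_in), (H, n_in)),
                    b1=np.zeros(H),
                    w2=rng.normal(0.0, 1.0 / math.sqrt(H), H),
                    b2=0.0)


def _pack(m: MLPModel) -> np.ndarray:
    return np.concatenate([m.W1.ravel(), m.b1, m.w2, [m.b2]])


def _unpack(w: np.ndarray, n_in: int, H: int) -> MLPModel:
    i = H * n_in
    return MLPModel(W1=w[:i].reshape(H, n_in), b1=w[i:i + H],
                    w2=w[i + H:i + 2 * H], b2=float(w[-1]))


def _mlp_grad(w: np.ndarray, X: np.ndarray, y: np.ndarray,
              n_in: int, H: int) -> tuple[float, np.ndarray]:
    """Sum-of-squares error 0.5*sum((out-y)^2) and its batch gradient."""
    m = _unpack(w, n_in, H)
    a1 = X @ m.W1.T + m.b1
    h = _sigmoid(a1)
    out = _sigmoid(h @ m.w2 + m.b2)
    err = out - y
    E = 0.5 * float(err @ err)
    d_out = err * out * (1.0 - out)          # (N,)
    g_w2 = d_out @ h
    g_b2 = d_out.sum()
    d_h = np.outer(d_out, m.w2) * h * (1.0 - h)   # (N, H)
    g_W1 = d_h.T @ X
    g_b1 = d_h.sum(axis=0)
    return E, np.concatenate([g_W1.ravel(), g_b1, g_w2, [g_b2]])


def train_mlp(features: FeatureMatrix, split: LearningSplit, H: int,
              cfg: RpropConfig | None = None,
              seed: int = 0) -> tuple[MLPModel, pd.DataFrame]:
    """Batch-Rprop training with validation-based early stopping.

    The returned model carries the weights achieving the best validation
    success rate seen during training (earliest epoch wins ties); the trace
    records train error, validation error and validation success per epoch.
    """
    cfg = cfg or RpropConfig()
    if len(split.train) == 0 or len(split.val) == 0:
        raise ValueError("train and validation partitions must be non-empty")
    X, y = features.X, features.y.astype(float)
    Xtr, ytr = X[split.train], y[split.train]
    Xval, yval = X[split.val], y[split.val]
    rng = np.random.default_rng(seed)
    model = _init_mlp(X.shape[1], H, rng)
    w = _pack(model)
    state = RpropState(w.size, cfg)
    best_w, best_success, best_epoch = w.copy(), -1.0, -1
    rows = []
    since_improve = 0
    for epoch in range(cfg.max_epochs):
        E_train, grad = _mlp_grad(w, Xtr, ytr, X.shape[1], H)
        w = w + state.step(grad)
        m = _unpack(w, X.shape[1], H)
        val_scores = m.scores(Xval)
        E_val = 0.5 * float((val_scores - yval) @ (val_scores - yval))
        val_success = 100.0 * float(np.mean((val_scores > 0.5) == (yval == 1.0)))
        rows.append({"epoch": epoch, "train_error": E_train,
                     "val_error": E_val, "val_success": val_success})
        if val_success > best_success:
            best_w, best_success, best_epoch = w.copy(), val_success, epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
    trace = pd.DataFrame(rows, columns=["epoch", "train_error", "val_error",
                                        "val_success"])
    return _unpack(best_w, X.shape[1], H), trace


def select_mlp(features: FeatureMatrix, split: LearningSplit,
               cfg: RpropConfig | None = None,
               H_grid: Sequence[int] = DEFAULT_H_GRID,
               restarts: int | None = None,
               seed: int = 0) -> tuple[MLPModel, pd.DataFrame]:
    """Sweep hidden-layer sizes with random restarts; keep the best model.

    Selection is by validation success; ties prefer the smaller hidden layer,
    then the lower restart index.
    """
    cfg = cfg or RpropConfig()
    if len(H_grid) == 0:
        raise ValueError("empty hidden-layer grid")
    restarts = restarts if restarts is not None else cfg.restarts
    rng = np.random.default_rng(seed)
    rows = []
    best = None  # (neg-success, H, restart, model)
    for H in H_grid:
        for r in range(restarts):
            sub_seed = int(rng.integers(0, 2**31))
            model, trace = train_mlp(features, split, H, cfg, seed=sub_seed)
            success = float(trace["val_success"].max()) if len(trace) else 0.0
            rows.append({"H": H, "restart": r, "val_success": success})
            key = (-success, H, r)
            if best is None or key < best[0]:
                best = (key, model)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

@dataclass
class SVMModel:
    """RBF SVM stored as its kernel expansion: f(x) = sum a_i K(x_i, x) + b."""

    support_vectors: np.ndarray  # (n_sv, q)
    dual_coef: np.ndarray        # alpha_i * y_i, (n_sv,)
    bias: float
    gamma: float
    C: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Decision function recomputed from the stored expansion."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError("feature dimension does not match model")
        d2 = (np.sum(X**2, axis=1)[:, None]
              + np.sum(self.support_vectors**2, axis=1)[None, :]
              - 2.0 * X @ self.support_vectors.T)
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.bias


def train_svm_rbf(features: FeatureMatrix, split: LearningSplit,
                  log2_gamma: float, log2_C: float) -> SVMModel:
    """Fit a soft-margin RBF SVM on the train partition.

    ``gamma = 2**log2_gamma`` and ``C = 2**log2_C`` (the exponent-grid
    convention: the kernel requires gamma > 0, so grid values are base-2
    exponents).  Labels are mass=+1, normal=-1.
    """
    X, y = features.X, np.where(features.y == 1, 1, -1)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    gamma, C = 2.0**log2_gamma, 2.0**log2_C
    clf = SVC(kernel="rbf", gamma=gamma, C=C)
    clf.fit(X[split.train], y[split.train])
    return SVMModel(support_vectors=clf.support_vectors_.copy(),
                    dual_coef=clf.dual_coef_.ravel().copy(),
                    bias=float(clf.intercept_[0]), gamma=gamma, C=C)


def grid_search_svm(features: FeatureMatrix, split: LearningSplit,
                    gamma_exps: Sequence[float] = DEFAULT_GAMMA_EXPS,
                    C_exps: Sequence[float] = DEFAULT_C_EXPS,
                    ) -> tuple[SVMModel, pd.DataFrame]:
    """Exhaustive (gamma, C) exponent grid, selected by validation success.

    Ties prefer the smaller C exponent, then the smaller gamma exponent.
    """
    if len(gamma_exps) == 0 or len(C_exps) == 0:
        raise ValueError("empty grid")
    yval = features.y[split.val]
    rows = []
    best = None  # (neg-success, C_exp, gamma_exp, model)
    for ce in C_exps:
        for ge in gamma_exps:
            model = train_svm_rbf(features, split, ge, ce)
            scores = model.decision_values(features.X[split.val])
            success = 100.0 * float(np.mean((scores > 0.0) == (yval == 1)))
            rows.append({"log2_gamma": ge, "log2_C": ce,
                         "val_success": success})
            key = (-success, ce, ge)
            if best is None or key < best[0]:
                best = (key, model)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shared prediction helpers
# ---------------------------------------------------------------------------

def predict_scores(model: "MLPModel | SVMModel", X: np.ndarray) -> np.ndarray:
    """Per-row score; higher = more mass-like.

    MLP: sigmoid output in (0, 1); SVM: raw decision value.
    """
    if isinstance(model, MLPModel):
        return model.scores(X)
    if isinstance(model, SVMModel):
        return model.decision_values(X)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def intermediate_threshold(model: "MLPModel | SVMModel") -> float:
    """Midpoint operating threshold: 0.5 for sigmoid scores, 0 for SVM."""
    return 0.5 if isinstance(model, MLPModel) else 0.0


def decide(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Label mass (1) iff score strictly exceeds the threshold."""
    return (np.asarray(scores) > threshold).astype(int)
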