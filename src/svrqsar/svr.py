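"""Epsilon-SVR fitting and cross-validated scoring.

Wraps the libsvm epsilon-SVR solver (via scikit-learn) behind a small
deterministic contract: the kernel is named by the libsvm integer code
(t = 0 linear, 1 polynomial of degree d, 2 radial basis, 3 sigmoid),
fold assignment is a seeded shuffle followed by contiguous blocks, and
model quality is the mean squared error of the pooled out-of-fold
predictions.

Hyperparameters C, epsilon and gamma default to C=10, epsilon=0.1,
gamma=1/D on z-scored descriptors; a log-grid search over them,
selected by the same cross-validation criterion, is available through
:func:`grid_search` for runs that want it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR as _SkSVR

__all__ = [
    "KernelSpec",
    "SVRConfig",
    "CVScheme",
    "FittedSVR",
    "enumerate_kernels",
    "fit_svr",
    "make_folds",
    "cv_predictions",
    "cv_mse",
    "grid_search",
]

_KERNEL_NAMES = {0: "linear", 1: "poly", 2: "rbf", 3: "sigmoid"}


@dataclass(frozen=True)
class KernelSpec:
    """libsvm kernel code ``t`` plus polynomial degree ``d`` (t=1 only)."""

    t: int = 2
    d: int = 3

    def __post_init__(self) -> None:
        if self.t not in _KERNEL_NAMES:
            raise ValueError(f"kernel code t={self.t} not in {sorted(_KERNEL_NAMES)}")
        if self.t == 1 and self.d < 2:
            raise ValueError("polynomial kernel requires degree d >= 2")

    @property
    def sklearn_name(self) -> str:
        return _KERNEL_NAMES[self.t]

    def label(self) -> str:
        return f"t={self.t}" + (f",d={self.d}" if self.t == 1 else "")


@dataclass(frozen=True)
class SVRConfig:
    """Epsilon-SVR hyperparameters.

    gamma="auto" means 1/D (number of descriptors in the model), the
    conventional default on standardized descriptors. ``tol`` fixes the
    solver tolerance so repeated fits are bitwise reproducible.
    """

    kernel: KernelSpec = field(default_factory=KernelSpec)
    C: float = 10.0
    epsilon: float = 0.1
    gamma: float | str = "auto"
    coef0: float = 0.0
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not (self.gamma == "auto" or (isinstance(self.gamma, (int, float)) and self.gamma > 0)):
            raise ValueError("gamma must be positive or 'auto'")

    def to_dict(self) -> dict:
        return {"kernel_t": self.kernel.t, "kernel_d": self.kernel.d, "C": self.C,
                "epsilon": self.epsilon, "gamma": self.gamma, "coef0": self.coef0,
                "tol": self.tol}

    @classmethod
    def from_dict(cls, d: dict) -> "SVRConfig":
        return cls(kernel=KernelSpec(t=int(d.get("kernel_t", 2)), d=int(d.get("kernel_d", 3))),
                   C=float(d.get("C", 10.0)), epsilon=float(d.get("epsilon", 0.1)),
                   gamma=d.get("gamma", "auto"), coef0=float(d.get("coef0", 0.0)),
                   tol=float(d.get("tol", 1e-6)))


@dataclass(frozen=True)
class CVScheme:
    """k-fold or leave-one-out cross-validation with seeded folds."""

    mode: str = "kfold"  # "kfold" | "loo"
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"kfold", "loo"}:
            raise ValueError("mode must be 'kfold' or 'loo'")
        if self.mode == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")

    def n_folds(self, n: int) -> int:
        if self.mode == "loo":
            return n
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds n={n}")
        return self.k

    @classmethod
    def parse(cls, text: str, seed: int = 0) -> "CVScheme":
        """Parse 'loo' or 'kfold:10'."""
        if text == "loo":
            return cls(mode="loo", seed=seed)
        if text.startswith("kfold"):
            k = int(text.split(":")[1]) if ":" in text else 10
            return cls(mode="kfold", k=k, seed=seed)
        raise ValueError(f"cannot parse CV scheme {text!r}")


@dataclass
class FittedSVR:
    """A trained epsilon-SVR with its training reference data.

    ``fitted_values`` are the model's predictions on its own training
    rows; calling :meth:`predict` on those rows reproduces them exactly.
    """

    config: SVRConfig
    estimator: object
    feature_names: list[str]
    X_train: pd.DataFrame
    y_train: pd.Series
    fitted_values: np.ndarray

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy()
        return self.estimator.predict(np.asarray(X, dtype=float))


def enumerate_kernels() -> list[KernelSpec]:
    """The five kernel configurations screened in an independent test:
    linear, polynomial of degrees 2 and 3, radial basis, sigmoid."""
    return [KernelSpec(t=0), KernelSpec(t=1, d=2), KernelSpec(t=1, d=3),
            KernelSpec(t=2), KernelSpec(t=3)]


def _make_estimator(cfg: SVRConfig, n_features: int) -> _SkSVR:
    gamma = 1.0 / n_features if cfg.gamma == "auto" else float(cfg.gamma)
    return _SkSVR(kernel=cfg.kernel.sklearn_name, degree=cfg.kernel.d, C=cfg.C,
                  epsilon=cfg.epsilon, gamma=gamma, coef0=cfg.coef0, tol=cfg.tol,
                  cache_size=200)


def fit_svr(X: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray,
            cfg: SVRConfig | None = None) -> FittedSVR:
    """Fit an epsilon-SVR; deterministic for fixed inputs and config."""
    cfg = cfg or SVRConfig()
    if isinstance(X, pd.DataFrame):
        names = X.columns.tolist()
        frame = X
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
        frame = pd.DataFrame(X, columns=names)
    y = pd.Series(np.asarray(y, dtype=float), index=frame.index)
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if frame.isna().any().any() or y.isna().any():
        raise ValueError("missing values in training data")
    est = _make_estimator(cfg, frame.shape[1])
    est.fit(frame.to_numpy(), y.to_numpy())
    fitted = est.predict(frame.to_numpy())
    return FittedSVR(config=cfg, estimator=est, feature_names=names,
                     X_train=frame, y_train=y, fitted_values=fitted)


def make_folds(n: int, cv: CVScheme) -> list[np.ndarray]:
    """Seeded shuffle then contiguous blocks; fold sizes differ by <= 1.

    Returns the held-out index arrays. LOO yields n singleton folds in
    row order (no shuffling needed: every row is held out exactly once).
    """
    if cv.mode == "loo":
        return [np.array([i]) for i in range(n)]
    k = cv.n_folds(n)
    order = np.random.default_rng(cv.seed).permutation(n)
    return [np.sort(block) for block in np.array_split(order, k)]


def cv_predictions(X: pd.DataFrame | np.ndarray, y: np.ndarray, cfg: SVRConfig,
                   cv: CVScheme, folds: list[np.ndarray] | None = None) -> np.ndarray:
    """Pooled out-of-fold predictions; each fold's model never sees its
    held-out rows. Pass precomputed ``folds`` to pair comparisons across
    candidate descriptor sets."""
    X = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if folds is None:
        folds = make_folds(n, cv)
    yhat = np.empty(n)
    for held_out in folds:
        mask = np.ones(n, dtype=bool)
        mask[held_out] = False
        est = _make_estimator(cfg, X.shape[1])
        est.fit(X[mask], y[mask])
        yhat[held_out] = est.predict(X[held_out])
    return yhat


def cv_mse(X: pd.DataFrame | np.ndarray, y: np.ndarray, cfg: SVRConfig,
           cv: CVScheme, folds: list[np.ndarray] | None = None) -> float:
    """Cross-validated mean squared error of pooled out-of-fold predictions."""
    y = np.asarray(y, dtype=float)
    yhat = cv_predictions(X, y, cfg, cv, folds=folds)
    return float(np.mean((y - yhat) ** 2))


def grid_search(X, y, cv: CVScheme, kernel: KernelSpec | None = None,
                C_grid=(0.1, 1.0, 10.0, 100.0, 1000.0),
                gamma_grid=(1e-3, 1e-2, 1e-1, 1.0),
                epsilon_grid=(0.01, 0.1, 0.5)) -> tuple[SVRConfig, float]:
    """Log-grid hyperparameter search scored by cross-validated MSE.

    Ties break toward the earlier grid point, so the result is
    deterministic. Returns (best config, its CV MSE).
    """
    kernel = kernel or KernelSpec(t=2)
    n = X.shape[0]
    folds = make_folds(n, cv)
    best: tuple[SVRConfig, float] | None = None
    for C in C_grid:
        for gamma in gamma_grid:
            for eps in epsilon_grid:
                cfg = SVRConfig(kernel=kernel, C=C, epsilon=eps, gamma=gamma)
                score = cv_mse(X, y, cfg, cv, folds=folds)
                if best is None or score < best[1]:
                    best = (cfg, score)
    return best
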