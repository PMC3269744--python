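"""Model-quality statistics for QSAR validation.

Three statistics are used throughout: the mean squared error of
prediction, the squared Pearson correlation between observed and
predicted activities (R^2), and the external-validation predictive
coefficient

    R^2_pred = 1 - SSE_test / sum((y_test - ybar_train)^2),

which compares the model against the naive predictor that always
returns the training-set mean. R^2_pred can be negative; the
conventional acceptability bar for an external test set is
R^2_pred > 0.6.

Undefined statistics (constant vectors, zero denominators) raise
:class:`UndefinedMetricError` instead of returning sentinel numbers, so
a selection loop can never silently consume a NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Metrics",
    "ModelEvaluation",
    "UndefinedMetricError",
    "mse",
    "r_squared",
    "r2_pred",
    "evaluate_model",
    "R2_PRED_ACCEPTABILITY",
]

#: minimum external R^2_pred for a model to be considered acceptable
R2_PRED_ACCEPTABILITY = 0.6


class UndefinedMetricError(ValueError):
    """A statistic is undefined for the given vectors (e.g. constant y)."""


@dataclass
class Metrics:
    mse: float
    r2: float
    r2_pred: float | None
    n: int
    y_bar_training: float | None = None

    @property
    def acceptable(self) -> bool | None:
        if self.r2_pred is None:
            return None
        return self.r2_pred > R2_PRED_ACCEPTABILITY

    def to_dict(self) -> dict:
        return {"mse": self.mse, "r2": self.r2, "r2_pred": self.r2_pred,
                "n": self.n, "y_bar_training": self.y_bar_training,
                "acceptable": self.acceptable}


@dataclass
class ModelEvaluation:
    """Test-set metrics plus training-set fitted metrics."""

    test: Metrics
    train: Metrics


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    return y, yhat


def mse(y, yhat) -> float:
    """Mean squared error, sum((y_i - yhat_i)^2) / n."""
    y, yhat = _pair(y, yhat)
    if y.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((y - yhat) ** 2))


def r_squared(y, yhat) -> float:
    """Squared Pearson correlation between observations and predictions.

    [sum((y-ybar)(yhat-yhatbar))]^2 / [sum((y-ybar)^2) sum((yhat-yhatbar)^2)];
    undefined (raises) when either vector is constant.
    """
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 points")
    dy = y - y.mean()
    dh = yhat - yhat.mean()
    denom = np.sum(dy**2) * np.sum(dh**2)
    if denom == 0:
        raise UndefinedMetricError("R^2 undefined: constant vector")
    return float(np.sum(dy * dh) ** 2 / denom)


def r2_pred(y_test, yhat_test, y_bar_training: float) -> float:
    """External predictive coefficient 1 - SSE / sum((y - ybar_train)^2).

    ``y_bar_training`` must come from training rows only. Equals 1 for a
    perfect predictor, 0 for the constant training-mean predictor, and
    is negative for anything worse than that baseline.
    """
    y, yhat = _pair(y_test, yhat_test)
    denom = float(np.sum((y - y_bar_training) ** 2))
    if denom == 0:
        raise UndefinedMetricError(
            "R^2_pred undefined: all test activities equal the training mean")
    return float(1.0 - np.sum((y - yhat) ** 2) / denom)


def evaluate_model(model, data) -> ModelEvaluation:
    """Score a fitted model on a modeling dataset.

    Test metrics use the model's predictions on the held-out compounds
    with the training-mean baseline for R^2_pred; training metrics are
    computed from the fitted values (no R^2_pred, which is an
    external-validation quantity).
    """
    if len(data.y_test) == 0:
        raise ValueError("dataset has no test compounds")
    y_bar_training = float(np.mean(data.y_train))
    yhat_test = model.predict(data.X_test)
    test = Metrics(
        mse=mse(data.y_test, yhat_test),
        r2=r_squared(data.y_test, yhat_test),
        r2_pred=r2_pred(data.y_test, yhat_test, y_bar_training),
        n=len(data.y_test),
        y_bar_training=y_bar_training,
    )
    yhat_train = model.predict(data.X_train)
    train = Metrics(
        mse=mse(data.y_train, yhat_train),
        r2=r_squared(data.y_train, yhat_train),
        r2_pred=None,
        n=len(data.y_train),
        y_bar_training=y_bar_training,
    )
    return ModelEvaluation(test=test, train=train)
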