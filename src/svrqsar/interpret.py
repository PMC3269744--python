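"""Interpretability for fitted SVR models: F-tests and effect curves.

For a nonlinear fit the regression and residual sums of squares do not
add to the total sum of squares, so the F statistics here are computed
directly from the fitted values rather than from R^2:

    SSR = sum((yhat_i - ybar)^2),  SSE = sum((y_i - yhat_i)^2)
    F_model = (SSR / p) / (SSE / (n - p - 1))         df (p, n-p-1)

Per-descriptor importance refits the model without one descriptor at a
time (identical hyperparameters) and measures the rise in residual sum
of squares:

    F_j = (SSE_without_j - SSE_full) / (SSE_full / (n - p - 1))   df (1, n-p-1)

Significance stars compare F against the upper critical values of the F
distribution at alpha = 0.05 (*) and 0.01 (**). When the fitted values
come from ordinary least squares these statistics reduce exactly to the
classical regression ANOVA F.

Single-factor effect curves trace the model's prediction along one
descriptor's observed training range with every other descriptor held
at its training mean, and label the direction of influence by the sign
of the Spearman correlation between grid and response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .svr import FittedSVR, SVRConfig, fit_svr

__all__ = [
    "DescriptorF",
    "FTestReport",
    "EffectCurve",
    "f_quantile",
    "model_significance",
    "descriptor_importance",
    "single_factor_effect",
]


def f_quantile(alpha: float, df1: int, df2: int) -> float:
    """Upper-alpha critical value of the F distribution."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be positive integers")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def _stars(f_value: float, df1: int, df2: int) -> str:
    if f_value >= f_quantile(0.01, df1, df2):
        return "**"
    if f_value >= f_quantile(0.05, df1, df2):
        return "*"
    return "ns"


@dataclass
class DescriptorF:
    name: str
    f_value: float
    df: tuple[int, int]
    significance: str          # "ns" | "*" | "**"
    floored: bool = False      # negative SS difference clamped to zero


@dataclass
class FTestReport:
    n: int
    p: int
    ssr: float
    sse: float
    f_model: float | None      # None flags a perfect fit (SSE = 0)
    df_model: tuple[int, int]
    model_significance: str | None = None
    per_descriptor: list[DescriptorF] | None = None
    perfect_fit: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n, "p": self.p, "ssr": self.ssr, "sse": self.sse,
            "f_model": self.f_model, "df_model": list(self.df_model),
            "model_significance": self.model_significance,
            "perfect_fit": self.perfect_fit,
            "per_descriptor": [
                {"name": d.name, "f_value": d.f_value, "df": list(d.df),
                 "significance": d.significance, "floored": d.floored}
                for d in (self.per_descriptor or [])
            ],
        }

    def importance_table(self) -> pd.DataFrame:
        """Descriptors sorted by decreasing F, with significance stars."""
        rows = [{"descriptor": d.name, "f_value": d.f_value,
                 "significance": d.significance} for d in (self.per_descriptor or [])]
        return (pd.DataFrame(rows, columns=["descriptor", "f_value", "significance"])
                .sort_values("f_value", ascending=False, kind="stable")
                .reset_index(drop=True))


def model_significance(model: FittedSVR, y, p: int | None = None) -> FTestReport:
    """Overall regression F-test from the model's fitted values.

    ``p`` defaults to the number of descriptors in the model; the
    residual degrees of freedom n - p - 1 must be positive. A zero SSE
    is reported as a perfect fit rather than an infinite F.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(model.fitted_values, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y length does not match the model's training rows")
    n = y.size
    if p is None:
        p = len(model.feature_names)
    df2 = n - p - 1
    if df2 < 1:
        raise ValueError(f"n - p - 1 = {df2} must be >= 1 (n={n}, p={p})")
    ssr = float(np.sum((yhat - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    if sse == 0:
        return FTestReport(n=n, p=p, ssr=ssr, sse=sse, f_model=None,
                           df_model=(p, df2), perfect_fit=True)
    f_model = (ssr / p) / (sse / df2)
    return FTestReport(n=n, p=p, ssr=ssr, sse=sse, f_model=f_model,
                       df_model=(p, df2), model_significance=_stars(f_model, p, df2))


def descriptor_importance(data, retained: list[str] | None = None,
                          svr: SVRConfig | None = None) -> FTestReport:
    """Per-descriptor importance F-tests by leave-one-descriptor-out refits.

    All refits use the same hyperparameters as the full model and the
    training rows only. A removal that happens to lower SSE (possible
    for a redundant descriptor under a nonlinear fit) is floored at
    F = 0 and flagged.
    """
    svr = svr or SVRConfig()
    names = retained if retained is not None else data.descriptor_names
    if len(names) < 2:
        raise ValueError("importance testing needs at least 2 descriptors")
    X = data.X_train[names]
    y = data.y_train.to_numpy()
    n, p = X.shape
    df2 = n - p - 1
    if df2 < 1:
        raise ValueError(f"n - p - 1 = {df2} must be >= 1 (n={n}, p={p})")

    # freeze gamma at the full model's resolved value so the reduced fits
    # use literally identical hyperparameters
    if svr.gamma == "auto":
        from dataclasses import replace
        svr = replace(svr, gamma=1.0 / p)
    full = fit_svr(X, y, svr)
    report = model_significance(full, y, p)
    sse_full = report.sse
    if sse_full == 0:
        report.per_descriptor = []
        return report

    per: list[DescriptorF] = []
    scale = sse_full / df2
    for name in names:
        reduced_names = [nm for nm in names if nm != name]
        reduced = fit_svr(X[reduced_names], y, svr)
        sse_red = float(np.sum((y - reduced.fitted_values) ** 2))
        f_j = (sse_red - sse_full) / scale
        floored = f_j < 0
        f_j = max(f_j, 0.0)
        per.append(DescriptorF(name=name, f_value=f_j, df=(1, df2),
                               significance=_stars(f_j, 1, df2), floored=floored))
    report.per_descriptor = per
    return report


@dataclass
class EffectCurve:
    """Predicted activity along one descriptor, others at training means."""

    descriptor: str
    grid: np.ndarray
    response: np.ndarray
    spearman_rho: float
    direction: str             # "positive" | "negative" | "flat"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"descriptor": self.descriptor, "x": self.grid,
                             "yhat": self.response})


def single_factor_effect(model: FittedSVR, data, descriptor: str,
                         g: int = 100, center: str = "mean",
                         flat_threshold: float = 0.1) -> EffectCurve:
    """Trace the model response along one descriptor's training range.

    The grid spans the descriptor's observed training minimum..maximum
    (g strictly increasing points); all other descriptors are fixed at
    their training means (or medians with ``center="median"``). The
    direction is the sign of the Spearman rank correlation between grid
    and response; |rho| below ``flat_threshold``, or a constant
    response, is labeled flat.
    """
    if descriptor not in model.feature_names:
        raise ValueError(f"descriptor {descriptor!r} not in the model")
    X_train = data.X_train[model.feature_names]
    lo, hi = float(X_train[descriptor].min()), float(X_train[descriptor].max())
    if not hi > lo:
        raise ValueError(f"descriptor {descriptor!r} is constant on training rows")
    grid = np.linspace(lo, hi, g)
    if center == "mean":
        base = X_train.mean()
    elif center == "median":
        base = X_train.median()
    else:
        raise ValueError("center must be 'mean' or 'median'")
    probe = pd.DataFrame(np.tile(base.to_numpy(), (g, 1)), columns=model.feature_names)
    probe[descriptor] = grid
    response = model.predict(probe)

    if np.ptp(response) < 1e-12:
        rho, direction = 0.0, "flat"
    else:
        rho = float(stats.spearmanr(grid, response).statistic)
        if abs(rho) < flat_threshold:
            direction = "flat"
        else:
            direction = "positive" if rho > 0 else "negative"
    return EffectCurve(descriptor=descriptor, grid=grid, response=response,
                       spearman_rho=rho, direction=direction)
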