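"""Nonlinear descriptor selection: coarse screening then backward elimination.

Two wrapper procedures built on cross-validated epsilon-SVR:

HDSN (high-dimensional descriptor selection, nonlinear) is the coarse
screen for thousands of descriptors. Each round scores every surviving
descriptor by the cross-validated MSE of a single-descriptor SVR,
retains the best fraction (never fewer than a floor), and tracks the
CV MSE of the full retained-set model; it stops at the round cap, at
the floor, or as soon as the full-model MSE worsens, in which case the
previous round's set is returned.

WDEM (worst descriptor elimination, multi-round) is the careful screen
for low-dimensional sets. Each round fits one leave-this-descriptor-out
model per survivor on identical folds and removes the descriptor whose
removal lowers the full-model CV MSE the most; it halts when no single
removal helps, and returns the set achieving the minimum full-model MSE
seen across rounds.

Within a selection run all candidate models are evaluated on one fixed
seeded fold assignment, so every MSE comparison — between candidates in
a round and between rounds for the stop rules — is paired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .svr import CVScheme, SVRConfig, cv_mse, make_folds

logger = logging.getLogger(__name__)

__all__ = [
    "HDSNConfig",
    "WDEMConfig",
    "SelectionRound",
    "SelectionTrace",
    "hdsn_screen",
    "wdem_eliminate",
    "select_descriptors",
]


@dataclass(frozen=True)
class HDSNConfig:
    retain_fraction: float = 0.5
    min_features: int = 10
    max_rounds: int = 10
    scoring: str = "single_descriptor_cv_mse"

    def __post_init__(self) -> None:
        if not 0 < self.retain_fraction < 1:
            raise ValueError("retain_fraction must be in (0, 1)")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")
        if self.scoring != "single_descriptor_cv_mse":
            raise ValueError(f"unknown scoring tag {self.scoring!r}")


@dataclass(frozen=True)
class WDEMConfig:
    max_rounds: int = 1000  # effective cap is the descriptor count

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class SelectionRound:
    method: str                 # "hdsn" | "wdem"
    index: int                  # 1-based round number within its method
    n_before: int
    n_after: int
    candidate_scores: dict[str, float]   # per-descriptor score this round
    eliminated: list[str]
    full_model_mse: float       # CV MSE of the retained set after the round
    reverted: bool = False      # round undone by an early-stop rule


@dataclass
class SelectionTrace:
    """Per-round record of a selection run; convertible to tidy form."""

    initial: list[str]
    rounds: list[SelectionRound] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    initial_mse: float | None = None

    @property
    def eliminated(self) -> list[str]:
        return [name for r in self.rounds if not r.reverted for name in r.eliminated]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (method, round, candidate, score, action) records."""
        rows = []
        for r in self.rounds:
            dropped = set(r.eliminated)
            drop_action = "eliminated_reverted" if r.reverted else "eliminated"
            for name, score in r.candidate_scores.items():
                rows.append({"method": r.method, "round": r.index, "candidate": name,
                             "score": score,
                             "action": drop_action if name in dropped else "retained"})
        return pd.DataFrame(rows, columns=["method", "round", "candidate", "score", "action"])

    def summary(self) -> dict:
        return {
            "n_initial": len(self.initial),
            "n_retained": len(self.retained),
            "retained": list(self.retained),
            "initial_mse": self.initial_mse,
            "rounds": [
                {"method": r.method, "round": r.index, "n_before": r.n_before,
                 "n_after": r.n_after, "eliminated": list(r.eliminated),
                 "full_model_mse": r.full_model_mse, "reverted": r.reverted}
                for r in self.rounds
            ],
        }

    def extend(self, other: "SelectionTrace") -> "SelectionTrace":
        combined = SelectionTrace(initial=self.initial, initial_mse=self.initial_mse)
        combined.rounds = self.rounds + other.rounds
        combined.retained = other.retained
        return combined


def _full_model_mse(data, names: list[str], svr: SVRConfig, cv: CVScheme,
                    folds) -> float:
    return cv_mse(data.X_train[names], data.y_train.to_numpy(), svr, cv, folds=folds)


def hdsn_screen(data, cfg: HDSNConfig | None = None, svr: SVRConfig | None = None,
                cv: CVScheme | None = None) -> tuple[list[str], SelectionTrace]:
    """Coarse round-wise screen of a high-dimensional descriptor matrix.

    Scores each surviving descriptor by the CV MSE of an SVR fit on that
    descriptor alone (training rows only), keeps the best
    ``retain_fraction`` (at least ``min_features``, ties broken toward
    earlier column order), and monitors the retained-set model's CV MSE
    for the early-stop rule. Returns the retained names in original
    column order plus the full trace.
    """
    cfg = cfg or HDSNConfig()
    svr = svr or SVRConfig()
    cv = cv or CVScheme(mode="kfold", k=10)
    names = data.descriptor_names
    if len(names) < cfg.min_features:
        raise ValueError(f"D={len(names)} below min_features={cfg.min_features}")

    y = data.y_train.to_numpy()
    folds = make_folds(len(y), cv)
    trace = SelectionTrace(initial=list(names))
    trace.initial_mse = _full_model_mse(data, names, svr, cv, folds)

    current = list(names)
    prev_mse = trace.initial_mse
    prev_set = list(current)
    score_cache: dict[str, float] = {}
    for round_idx in range(1, cfg.max_rounds + 1):
        if len(current) <= cfg.min_features:
            break
        # single-descriptor scores do not depend on the rest of the set and
        # the folds are fixed for the whole run: score each descriptor once
        for name in current:
            if name not in score_cache:
                score_cache[name] = cv_mse(data.X_train[[name]], y, svr, cv,
                                           folds=folds)
        scores = {name: score_cache[name] for name in current}
        n_keep = max(cfg.min_features, math.ceil(cfg.retain_fraction * len(current)))
        # stable sort on (score, column position): ties keep earlier columns
        order = sorted(current, key=lambda nm: (scores[nm], current.index(nm)))
        keep = set(order[:n_keep])
        retained = [nm for nm in current if nm in keep]
        eliminated = [nm for nm in current if nm not in keep]
        full_mse = _full_model_mse(data, retained, svr, cv, folds)
        trace.rounds.append(SelectionRound(
            method="hdsn", index=round_idx, n_before=len(current),
            n_after=len(retained), candidate_scores=scores,
            eliminated=eliminated, full_model_mse=full_mse))
        logger.info("HDSN round %d: %d -> %d descriptors, full-model CV MSE %.5f",
                    round_idx, len(current), len(retained), full_mse)
        if full_mse > prev_mse:
            # this round hurt the model: revert to the previous set
            logger.info("HDSN stop: MSE worsened (%.5f > %.5f); reverting round %d",
                        full_mse, prev_mse, round_idx)
            trace.rounds[-1].reverted = True
            current = prev_set
            break
        prev_set = list(retained)
        prev_mse = full_mse
        current = retained

    trace.retained = current
    return current, trace


def wdem_eliminate(data, cfg: WDEMConfig | None = None, svr: SVRConfig | None = None,
                   cv: CVScheme | None = None) -> tuple[list[str], SelectionTrace]:
    """Backward elimination, one worst descriptor per round.

    Each round evaluates, on identical folds, the CV MSE of the model
    with each single descriptor left out; the removal giving the lowest
    MSE is applied provided it does not exceed the current full-model
    MSE, otherwise the procedure halts. Equal candidate MSEs eliminate
    the descriptor later in column order. Returns the set with the
    minimum full-model MSE observed over all rounds.
    """
    cfg = cfg or WDEMConfig()
    svr = svr or SVRConfig()
    cv = cv or CVScheme(mode="kfold", k=10)
    current = list(data.descriptor_names)
    y = data.y_train.to_numpy()
    folds = make_folds(len(y), cv)

    trace = SelectionTrace(initial=list(current))
    if len(current) < 2:
        trace.retained = current
        trace.initial_mse = (_full_model_mse(data, current, svr, cv, folds)
                             if current else None)
        return current, trace

    def round_cfg(p: int) -> SVRConfig:
        # freeze gamma at the current model's resolved value so every
        # leave-one-out candidate in a round is fit with literally the same
        # hyperparameters as the full model it is compared against
        if svr.gamma == "auto":
            return replace(svr, gamma=1.0 / p)
        return svr

    current_mse = _full_model_mse(data, current, round_cfg(len(current)), cv, folds)
    trace.initial_mse = current_mse
    best_set, best_mse = list(current), current_mse

    for round_idx in range(1, cfg.max_rounds + 1):
        if len(current) < 2:
            break
        cfg_r = round_cfg(len(current))
        if round_idx > 1:
            current_mse = _full_model_mse(data, current, cfg_r, cv, folds)
        scores: dict[str, float] = {}
        worst_name, worst_mse = None, np.inf
        for name in current:
            reduced = [nm for nm in current if nm != name]
            m = cv_mse(data.X_train[reduced], y, cfg_r, cv, folds=folds)
            scores[name] = m
            if m <= worst_mse:  # <= : ties remove the later column
                worst_name, worst_mse = name, m
        if worst_mse > current_mse:
            logger.info("WDEM stop after %d round(s): best removal MSE %.5f > "
                        "current %.5f", round_idx - 1, worst_mse, current_mse)
            break
        current = [nm for nm in current if nm != worst_name]
        trace.rounds.append(SelectionRound(
            method="wdem", index=round_idx, n_before=len(current) + 1,
            n_after=len(current), candidate_scores=scores,
            eliminated=[worst_name], full_model_mse=worst_mse))
        logger.info("WDEM round %d: eliminated %s, full-model CV MSE %.5f",
                    round_idx, worst_name, worst_mse)
        if worst_mse <= best_mse:
            best_set, best_mse = list(current), worst_mse

    trace.retained = best_set
    return best_set, trace


def select_descriptors(data, hdsn_cfg: HDSNConfig | None = None,
                       wdem_cfg: WDEMConfig | None = None,
                       svr: SVRConfig | None = None, cv: CVScheme | None = None,
                       low_dim_threshold: int = 30) -> tuple[list[str], SelectionTrace]:
    """HDSN coarse screen followed by WDEM careful elimination.

    The HDSN stage is skipped when the input is already low-dimensional
    (D <= ``low_dim_threshold``), matching direct backward elimination
    on a literature-sized descriptor set.
    """
    if len(data.descriptor_names) > low_dim_threshold:
        survivors, hdsn_trace = hdsn_screen(data, hdsn_cfg, svr, cv)
        reduced = data.subset(survivors)
    else:
        logger.info("D=%d <= %d: skipping HDSN, WDEM only",
                    len(data.descriptor_names), low_dim_threshold)
        hdsn_trace = SelectionTrace(initial=list(data.descriptor_names),
                                    retained=list(data.descriptor_names))
        reduced = data
    retained, wdem_trace = wdem_eliminate(reduced, wdem_cfg, svr, cv)
    if hdsn_trace.initial_mse is not None and wdem_trace.initial_mse is None:
        wdem_trace.initial_mse = hdsn_trace.initial_mse
    return retained, hdsn_trace.extend(wdem_trace)
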