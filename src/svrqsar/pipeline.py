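"""End-to-end QSAR workflow orchestration.

Stage order is fixed: load (or simulate) -> align & scale -> descriptor
selection (the coarse screen is skipped for low-dimensional input) ->
kernel choice by leave-one-out CV over the five standard kernels ->
final fit on all training rows -> test-set evaluation -> F-test
interpretability and single-factor effect directions -> report.

No stage reads test activities before the evaluation stage; scaling and
selection use training rows only. Given one config and seed the run
report is byte-identical across repeats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import reference
from .datamodel import (ModelingDataset, make_modeling_dataset,
                        read_activity_table, read_descriptor_table)
from .interpret import descriptor_importance, single_factor_effect
from .metrics import ModelEvaluation, evaluate_model
from .selection import HDSNConfig, SelectionTrace, WDEMConfig, select_descriptors
from .svr import CVScheme, FittedSVR, SVRConfig, cv_mse, enumerate_kernels, fit_svr
from .synthetic import SyntheticSpec, generate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Exactly one of ``synthetic`` or (``descriptor_file``,
    ``activity_file``) supplies the data. ``seed`` drives fold
    assignment and, for synthetic input, data generation.
    """

    descriptor_file: str | None = None
    activity_file: str | None = None
    synthetic: SyntheticSpec | None = None
    id_column: str = "compound"
    scale: bool = True
    svr: SVRConfig = field(default_factory=SVRConfig)
    selection_cv_folds: int = 10
    hdsn: HDSNConfig = field(default_factory=HDSNConfig)
    wdem: WDEMConfig = field(default_factory=WDEMConfig)
    low_dim_threshold: int = 30
    kernel_selection_cv: str = "loo"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        synthetic = SyntheticSpec(**raw["synthetic"]) if "synthetic" in raw else None
        svr = SVRConfig.from_dict(raw.get("svr", {}))
        hdsn = HDSNConfig(**raw.get("hdsn", {}))
        wdem = WDEMConfig(**raw.get("wdem", {}))
        return cls(
            descriptor_file=raw.get("descriptor_file"),
            activity_file=raw.get("activity_file"),
            synthetic=synthetic, id_column=raw.get("id_column", "compound"),
            scale=raw.get("scale", True), svr=svr,
            selection_cv_folds=raw.get("selection_cv_folds", 10),
            hdsn=hdsn, wdem=wdem,
            low_dim_threshold=raw.get("low_dim_threshold", 30),
            kernel_selection_cv=raw.get("kernel_selection_cv", "loo"),
            seed=raw.get("seed", 0),
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = {
            "descriptor_file": self.descriptor_file,
            "activity_file": self.activity_file,
            "synthetic": asdict(self.synthetic) if self.synthetic else None,
            "id_column": self.id_column, "scale": self.scale,
            "svr": self.svr.to_dict(),
            "selection_cv_folds": self.selection_cv_folds,
            "hdsn": asdict(self.hdsn), "wdem": asdict(self.wdem),
            "low_dim_threshold": self.low_dim_threshold,
            "kernel_selection_cv": self.kernel_selection_cv, "seed": self.seed,
        }
        return d


@dataclass
class RunReport:
    config: dict
    selection: dict
    retained: list[str]
    kernel_cv: dict            # per-kernel LOO CV MSE on the retained set
    chosen_kernel: str
    evaluation: dict           # train/test metrics
    ftest: dict
    effect_directions: dict[str, str]
    literature_comparators: list[dict]
    model: FittedSVR | None = None
    dataset: ModelingDataset | None = None
    trace: SelectionTrace | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "selection": self.selection,
            "retained": self.retained,
            "kernel_cv": self.kernel_cv,
            "chosen_kernel": self.chosen_kernel,
            "evaluation": self.evaluation,
            "ftest": self.ftest,
            "effect_directions": self.effect_directions,
            "literature_comparators": self.literature_comparators,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @property
    def acceptable(self) -> bool:
        return bool(self.evaluation["test"]["acceptable"])


def _load_dataset(cfg: PipelineConfig) -> ModelingDataset:
    if cfg.synthetic is not None:
        matrix, activities, _ = generate(cfg.synthetic)
    elif cfg.descriptor_file and cfg.activity_file:
        matrix = read_descriptor_table(cfg.descriptor_file, id_column=cfg.id_column)
        activities = read_activity_table(cfg.activity_file)
    else:
        raise ValueError("config must provide a synthetic spec or both "
                         "descriptor_file and activity_file")
    return make_modeling_dataset(matrix, activities, scale=cfg.scale)


def run_pipeline(config: PipelineConfig | dict | str | Path) -> RunReport:
    """Execute the full workflow and assemble a machine-readable report."""
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = config

    logger.info("stage 1/6: load data")
    data = _load_dataset(cfg)
    logger.info("dataset: %d train / %d test compounds, %d descriptors",
                data.n_train, len(data.y_test), len(data.descriptor_names))

    logger.info("stage 2/6: descriptor selection")
    sel_cv = CVScheme(mode="kfold",
                      k=min(cfg.selection_cv_folds, data.n_train), seed=cfg.seed)
    retained, trace = select_descriptors(
        data, hdsn_cfg=cfg.hdsn, wdem_cfg=cfg.wdem, svr=cfg.svr, cv=sel_cv,
        low_dim_threshold=cfg.low_dim_threshold)
    reduced = data.subset(retained)

    logger.info("stage 3/6: kernel choice over the five standard kernels (%s CV)",
                cfg.kernel_selection_cv)
    kernel_cv_scheme = CVScheme.parse(cfg.kernel_selection_cv, seed=cfg.seed)
    kernel_cv: dict[str, float] = {}
    best_label, best_mse = None, np.inf
    from dataclasses import replace
    for kspec in enumerate_kernels():
        kcfg = replace(cfg.svr, kernel=kspec)
        m = cv_mse(reduced.X_train, reduced.y_train.to_numpy(), kcfg, kernel_cv_scheme)
        kernel_cv[kspec.label()] = m
        if m < best_mse:
            best_label, best_mse = kspec.label(), m
            best_cfg = kcfg

    logger.info("stage 4/6: final fit (%s)", best_label)
    model = fit_svr(reduced.X_train, reduced.y_train, best_cfg)

    logger.info("stage 5/6: evaluation")
    evaluation: ModelEvaluation = evaluate_model(model, reduced)

    logger.info("stage 6/6: interpretability")
    n, p = reduced.X_train.shape
    ftest_dict: dict
    if n - p - 1 >= 1 and p >= 2:
        ftest = descriptor_importance(reduced, retained, best_cfg)
        ftest_dict = ftest.to_dict()
    else:
        ftest_dict = {"skipped": f"n-p-1={n - p - 1} leaves no residual df"}
    directions = {}
    for name in retained:
        try:
            directions[name] = single_factor_effect(model, reduced, name).direction
        except ValueError:
            directions[name] = "undefined"

    report = RunReport(
        config=cfg.to_dict(),
        selection=trace.summary(),
        retained=list(retained),
        kernel_cv=kernel_cv,
        chosen_kernel=best_label,
        evaluation={"test": evaluation.test.to_dict(),
                    "train": evaluation.train.to_dict()},
        ftest=ftest_dict,
        effect_directions=directions,
        literature_comparators=reference.comparator_table(),
        model=model, dataset=reduced, trace=trace,
    )
    logger.info("done: %d descriptors retained, test R^2_pred=%.3f (acceptable: %s)",
                len(retained), evaluation.test.r2_pred, report.acceptable)
    return report
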