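"""Descriptor matrices, activity tables and train/test plumbing.

The central containers mirror what a QSAR practitioner works with: a
compounds x descriptors matrix of numeric molecular descriptors, an
activity table of pIC50 values with a train/test partition, and an
aligned, optionally z-scored modeling dataset whose scaling parameters
are learned on training rows only (test rows are transformed with the
stored training statistics, never refit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorMatrix",
    "ActivityTable",
    "ModelingDataset",
    "read_descriptor_table",
    "write_descriptor_table",
    "load_arc111_fixture",
    "ic50_to_pic50",
    "pic50_to_ic50",
    "make_modeling_dataset",
]


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class DescriptorMatrix:
    """Compounds x named molecular descriptors, no missing entries.

    ``frame`` is indexed by compound ID with one float column per
    descriptor; IDs and descriptor names are unique.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.frame.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate compound IDs: {dups}")
        cols = self.frame.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate descriptor names: {dups}")
        if self.frame.isna().any().any():
            bad = self.frame.columns[self.frame.isna().any()].tolist()
            raise DataValidationError(
                f"missing values are not allowed (columns {bad}); "
                "drop or repair them before loading"
            )
        self.frame = self.frame.astype(float)

    @property
    def compound_ids(self) -> list:
        return self.frame.index.tolist()

    @property
    def descriptor_names(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_compounds(self) -> int:
        return self.frame.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.frame.shape[1]


@dataclass
class ActivityTable:
    """pIC50 activities with a train/test/theoretical partition.

    Theoretical compounds carry no experimental activity; any published
    model prediction for them lives in ``reference_pred`` as metadata,
    never as a fitting target.
    """

    frame: pd.DataFrame  # columns: pIC50, split [, reference_pred]; index = compound

    def __post_init__(self) -> None:
        required = {"pIC50", "split"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataValidationError(f"activity table missing columns: {sorted(missing)}")
        bad = set(self.frame["split"].unique()) - {"train", "test", "theoretical"}
        if bad:
            raise DataValidationError(f"unknown split labels: {sorted(bad)}")
        if self.frame.index.has_duplicates:
            raise DataValidationError("duplicate compound IDs in activity table")
        experimental = self.frame["split"] != "theoretical"
        if not np.isfinite(self.frame.loc[experimental, "pIC50"].astype(float)).all():
            raise DataValidationError("non-finite pIC50 for an experimental compound")

    def ids(self, split: str) -> list:
        return self.frame.index[self.frame["split"] == split].tolist()

    @property
    def train_ids(self) -> list:
        return self.ids("train")

    @property
    def test_ids(self) -> list:
        return self.ids("test")

    def activities(self, split: str) -> pd.Series:
        return self.frame.loc[self.frame["split"] == split, "pIC50"].astype(float)


@dataclass
class Scaler:
    """Per-descriptor center/scale learned from training rows only."""

    center: pd.Series
    scale: pd.Series

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return (frame - self.center) / self.scale


@dataclass
class ModelingDataset:
    """Aligned train/test slices ready for SVR fitting.

    Scaling statistics come exclusively from training rows; constant
    (zero training variance) descriptors are removed before scaling.
    """

    X_train: pd.DataFrame
    y_train: pd.Series
    X_test: pd.DataFrame
    y_test: pd.Series
    scaler: Scaler | None = None
    removed_constant: list[str] = field(default_factory=list)

    @property
    def descriptor_names(self) -> list[str]:
        return self.X_train.columns.tolist()

    @property
    def n_train(self) -> int:
        return len(self.y_train)

    def subset(self, names: list[str]) -> "ModelingDataset":
        """Restrict to a descriptor subset, preserving column order."""
        keep = [c for c in self.X_train.columns if c in set(names)]
        return ModelingDataset(
            X_train=self.X_train[keep],
            y_train=self.y_train,
            X_test=self.X_test[keep],
            y_test=self.y_test,
            scaler=self.scaler,
            removed_constant=self.removed_constant,
        )


def read_descriptor_table(path: str | Path, id_column: str = "compound") -> DescriptorMatrix:
    """Load a delimited descriptor table (comma or tab, auto-detected).

    One row per compound, header row of descriptor names, one ID column.
    Duplicate compound IDs, duplicate descriptor names, missing or
    non-numeric cells are hard errors naming the offending row/column.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    sep = "\t" if header_line.count("\t") >= header_line.count(",") else ","
    header = header_line.split(sep)
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:  # pandas would silently mangle these to name.1, name.2, ...
        raise DataValidationError(f"duplicate descriptor names in header: {dups}")
    frame = pd.read_csv(path, sep=sep)
    if id_column not in frame.columns:
        raise DataValidationError(f"ID column {id_column!r} not found in {path.name}")
    frame = frame.set_index(id_column)
    for col in frame.columns:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            bad_rows = frame.index[
                pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            ].tolist()
            raise DataValidationError(
                f"non-numeric value in column {col!r}, rows {bad_rows}"
            ) from exc
    return DescriptorMatrix(frame)


def write_descriptor_table(matrix: DescriptorMatrix, path: str | Path,
                           id_column: str = "compound") -> None:
    """Write a descriptor matrix as CSV; round-trips through
    :func:`read_descriptor_table` losslessly (full float repr)."""
    matrix.frame.rename_axis(id_column).to_csv(path)


def read_activity_table(path: str | Path) -> ActivityTable:
    """Load an activity CSV with columns compound, pIC50, split."""
    frame = pd.read_csv(path).set_index("compound")
    return ActivityTable(frame)


def write_activity_table(table: ActivityTable, path: str | Path) -> None:
    table.frame.rename_axis("compound").to_csv(path)


def load_arc111_fixture() -> ActivityTable:
    """The packaged ARC-111 analogue activity table.

    22 experimental dibenzonaphthyridinone analogues assayed against the
    RPMI8402 T-cell leukemia line (pIC50 6.071-9.523; 18 train / 4 test,
    test set = compounds 8, 10, 15, 20), plus 12 theoretical analogues
    whose published model predictions are kept as reference metadata.
    """
    with resources.files("svrqsar.data").joinpath("arc111_activities.csv").open() as fh:
        frame = pd.read_csv(fh, dtype={"compound": str}).set_index("compound")
    return ActivityTable(frame)


def ic50_to_pic50(ic50_um: float) -> float:
    """Convert an IC50 in micromolar to pIC50 = -log10 of the molar IC50.

    Equivalently ``6 - log10(IC50[uM])``: 1 uM -> 6.0, 1 nM -> 9.0.
    """
    ic50_um = np.asarray(ic50_um, dtype=float)
    if np.any(ic50_um <= 0):
        raise ValueError("IC50 must be positive")
    out = 6.0 - np.log10(ic50_um)
    return float(out) if out.ndim == 0 else out


def pic50_to_ic50(pic50: float) -> float:
    """Inverse of :func:`ic50_to_pic50`; returns IC50 in micromolar."""
    pic50 = np.asarray(pic50, dtype=float)
    out = np.power(10.0, 6.0 - pic50)
    return float(out) if out.ndim == 0 else out


def make_modeling_dataset(X: DescriptorMatrix, activities: ActivityTable,
                          scale: bool = True) -> ModelingDataset:
    """Align a descriptor matrix with an activity table and z-score it.

    Scaling (when enabled) uses training-row means and standard
    deviations only; descriptors with zero training variance are removed
    first, with the removal logged. Compounds present in the activity
    table but absent from the matrix are a hard error.
    """
    train_ids = activities.train_ids
    test_ids = activities.test_ids
    missing = [c for c in train_ids + test_ids if c not in X.frame.index]
    if missing:
        raise DataValidationError(f"compounds missing from descriptor matrix: {missing}")

    X_train = X.frame.loc[train_ids]
    X_test = X.frame.loc[test_ids]
    y_train = activities.frame.loc[train_ids, "pIC50"].astype(float)
    y_test = activities.frame.loc[test_ids, "pIC50"].astype(float)

    train_sd = X_train.std(ddof=0)
    constant = train_sd.index[train_sd == 0].tolist()
    if constant:
        logger.info("removing %d constant descriptor(s): %s", len(constant),
                    constant if len(constant) <= 20 else constant[:20] + ["..."])
        X_train = X_train.drop(columns=constant)
        X_test = X_test.drop(columns=constant)

    scaler = None
    if scale:
        scaler = Scaler(center=X_train.mean(), scale=X_train.std(ddof=0))
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)

    return ModelingDataset(X_train=X_train, y_train=y_train, X_test=X_test,
                           y_test=y_test, scaler=scaler, removed_constant=constant)
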