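"""Tabular containers and CSV readers/writers for the pipeline.

All exchange formats are comma-separated UTF-8 text with a mandatory
header row and a decimal point. Batch group membership (raw vs
processed herb material) is inferred from the batch-ID prefix used in
the cohort naming scheme (``S`` for raw, ``Z`` for processed) unless an
explicit mapping is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, FormatError, JoinError

GROUP_RAW = "raw"
GROUP_PROCESSED = "processed"
GROUP_QC = "QC"

CELL_LINES = ("L02", "HepG2")


def infer_group(batch_id: str) -> str:
    """Map a batch ID to its group by prefix: S -> raw, Z -> processed."""
    prefix = str(batch_id)[:1].upper()
    if prefix == "S":
        return GROUP_RAW
    if prefix == "Z":
        return GROUP_PROCESSED
    if str(batch_id).upper().startswith("QC"):
        return GROUP_QC
    raise FormatError(
        f"cannot infer group for batch {batch_id!r}; provide an explicit group_map"
    )


@dataclass
class QuantTable:
    """Batches x compounds peak-area table with a group label per batch.

    ``areas`` is indexed by batch ID with one column per quantified
    compound, preserving the panel's compound order; ``groups`` is a
    parallel Series of ``raw`` / ``processed`` labels.
    """

    areas: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        self.areas = self.areas.astype(float)
        self.groups = self.groups.reindex(self.areas.index)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise FormatError(f"no group label for batches {missing}")
        if (self.areas.values < 0).any():
            bad = self.areas.columns[(self.areas.values < 0).any(axis=0)].tolist()
            raise DataValidationError(f"negative peak areas in columns {bad}")

    @property
    def batches(self) -> list:
        return list(self.areas.index)

    @property
    def compounds(self) -> list:
        return list(self.areas.columns)

    def group_frame(self, group: str) -> pd.DataFrame:
        return self.areas.loc[self.groups == group]

    def n_in_group(self, group: str) -> int:
        return int((self.groups == group).sum())

    def standardized(self) -> pd.DataFrame:
        """Per-compound z-scored areas (the heat-map matrix)."""
        sd = self.areas.std(axis=0, ddof=1).replace(0.0, np.nan)
        return (self.areas - self.areas.mean(axis=0)) / sd


@dataclass
class ToxicityTable:
    """Per-batch, per-cell-line mean IC50 values (ug/ml).

    Long format: one row per (batch, cell line) with the replicate-mean
    IC50, its reciprocal (the potency scale used as the gray relational
    reference series) and a censoring flag for values extrapolated
    beyond the top tested concentration.
    """

    data: pd.DataFrame  # columns: batch, cell_line, ic50, censored

    def __post_init__(self):
        required = {"batch", "cell_line", "ic50"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"toxicity table is missing columns {sorted(missing)}")
        if "censored" not in self.data.columns:
            self.data = self.data.assign(censored=False)
        self.data = self.data.reset_index(drop=True)
        self.data["ic50"] = self.data["ic50"].astype(float)
        if (self.data["ic50"] <= 0).any():
            raise DataValidationError("IC50 values must be strictly positive")
        self.data["censored"] = self.data["censored"].astype(bool)

    @property
    def cell_lines(self) -> list:
        return list(pd.unique(self.data["cell_line"]))

    def ic50_series(self, cell_line: str) -> pd.Series:
        sub = self.data[self.data["cell_line"] == cell_line]
        if sub.empty:
            raise JoinError(f"no IC50 entries for cell line {cell_line!r}")
        if sub["batch"].duplicated().any():
            # replicate-level rows: collapse to the arithmetic mean per batch
            return sub.groupby("batch", sort=False)["ic50"].mean()
        return sub.set_index("batch")["ic50"]

    def inverse_ic50_series(self, cell_line: str) -> pd.Series:
        return 1.0 / self.ic50_series(cell_line)

    def frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out["inv_ic50"] = 1.0 / out["ic50"]
        return out


@dataclass
class FeatureMatrix:
    """Samples x untargeted-feature intensity matrix with group labels.

    Feature IDs follow the retention-time_m/z convention
    (e.g. ``4.88_289.0716``); groups are raw / processed / QC.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    truth: pd.Series | None = field(default=None)  # planted-differential flags

    def __post_init__(self):
        if self.intensities.columns.duplicated().any():
            dupes = self.intensities.columns[self.intensities.columns.duplicated()]
            raise FormatError(f"duplicate feature IDs: {list(dupes)}")
        self.intensities = self.intensities.astype(float)
        if (self.intensities.values < 0).any():
            raise DataValidationError("intensities must be non-negative")
        self.groups = self.groups.reindex(self.intensities.index)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise FormatError(f"no group label for samples {missing}")

    @property
    def features(self) -> list:
        return list(self.intensities.columns)

    def without_qc(self) -> "FeatureMatrix":
        keep = self.groups != GROUP_QC
        return FeatureMatrix(self.intensities.loc[keep], self.groups.loc[keep], self.truth)


# ---------------------------------------------------------------------------
# CSV readers / writers


def read_quant_table(path, group_map=None, expected_compounds=None) -> QuantTable:
    """Read a batches x compounds CSV (first column = batch ID).

    ``expected_compounds`` optionally pins the panel: a missing column
    is a format error; unknown extra columns are dropped with a warning.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    if frame.empty or frame.shape[1] == 0:
        raise FormatError(f"{path} contains no compound columns")
    if expected_compounds is not None:
        expected = list(expected_compounds)
        missing = [c for c in expected if c not in frame.columns]
        if missing:
            raise FormatError(f"{path} is missing compound columns {missing}")
        extra = [c for c in frame.columns if c not in expected]
        if extra:
            warnings.warn(f"ignoring unknown columns {extra} in {path}", stacklevel=2)
            frame = frame[expected]
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path} contains non-numeric peak areas: {exc}") from exc
    groups = _resolve_groups(frame.index, group_map)
    return QuantTable(frame, groups)


def _resolve_groups(index, group_map) -> pd.Series:
    if group_map is not None:
        labels = {}
        for batch in index:
            if batch not in group_map:
                raise FormatError(f"group_map has no entry for batch {batch!r}")
            labels[batch] = group_map[batch]
        return pd.Series(labels)
    return pd.Series({batch: infer_group(batch) for batch in index})


def write_quant_table(table: QuantTable, path) -> None:
    table.areas.to_csv(path, index_label="batch")


def read_toxicity_table(path) -> ToxicityTable:
    """Read a long-format IC50 CSV (batch, cell_line, ic50[, censored]).

    Accepts either one row per batch/cell line (the replicate mean) or
    one row per replicate; replicate rows are averaged on access.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    return ToxicityTable(frame)


def write_toxicity_table(table: ToxicityTable, path) -> None:
    table.frame().to_csv(path, index=False)


def read_feature_matrix(path, group_map=None) -> FeatureMatrix:
    """Read a samples x features intensity CSV with a ``group`` column."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    if "group" in frame.columns:
        groups = frame.pop("group").astype(str)
    else:
        groups = _resolve_groups(frame.index, group_map)
    return FeatureMatrix(frame.astype(float), groups)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    out = matrix.intensities.copy()
    out.insert(0, "group", matrix.groups)
    out.to_csv(path, index_label="sample")


def read_plate_table(path) -> pd.DataFrame:
    """Read a plate CSV: batch, cell_line, replicate, role, concentration, OD.

    ``role`` is ``sample`` for treated wells, ``NC`` for the negative
    (vehicle) control and ``STSP`` for the full-kill positive control;
    control rows leave ``concentration`` empty.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"batch", "cell_line", "replicate", "role", "concentration", "OD"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"plate table is missing columns {sorted(missing)}")
    return frame


def check_batches_match(quant: QuantTable, toxicity: ToxicityTable) -> None:
    """Raise :class:`JoinError` when the two tables disagree on batches."""
    quant_batches = set(quant.batches)
    problems = []
    for cell_line in toxicity.cell_lines:
        tox_batches = set(toxicity.ic50_series(cell_line).index)
        missing_tox = sorted(quant_batches - tox_batches)
        missing_quant = sorted(tox_batches - quant_batches)
        if missing_tox:
            problems.append(f"{cell_line}: no IC50 for batches {missing_tox}")
        if missing_quant:
            problems.append(f"{cell_line}: no peak areas for batches {missing_quant}")
    if problems:
        raise JoinError("; ".join(problems), missing=problems)
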