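"""File formats and run configuration.

Scan files are plain CSV with header ``stimulus_index,intensity_mA,amplitude_mV``
(one row per stimulus, 1-based index in delivery order); cohort tables are TSV
with the per-subject columns of the study table.  Floats are written with 6
significant digits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_stats import CohortTable, NUMERIC_COLUMNS
from .d50 import CMAPScan

__all__ = [
    "ScanParseError",
    "read_scan",
    "write_scan",
    "read_cohort",
    "write_cohort",
    "load_table1_fixture",
    "RunConfig",
]

SCAN_COLUMNS = ["stimulus_index", "intensity_mA", "amplitude_mV"]
COHORT_REQUIRED = ["subject_id", "group"]


class ScanParseError(ValueError):
    """Malformed scan or cohort file."""


def _check_columns(found, expected, path) -> None:
    missing = [c for c in expected if c not in found]
    extra = [c for c in found if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns {missing}")
        if extra:
            parts.append(f"unexpected columns {extra}")
        raise ScanParseError(f"{path}: " + "; ".join(parts))


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
        raise ScanParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
    return vals.to_numpy()


def read_scan(path) -> CMAPScan:
    """Read a scan CSV; raises :class:`ScanParseError` naming the offending
    column/row on malformed input."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ScanParseError(f"{path}: file is empty") from None
    _check_columns(list(df.columns), SCAN_COLUMNS, path)
    if df[SCAN_COLUMNS].isna().any().any():
        col = df.columns[df[SCAN_COLUMNS].isna().any()][0]
        row = int(np.flatnonzero(df[col].isna())[0]) + 2
        raise ScanParseError(f"{path}: empty cell in column {col!r} at line {row}")
    idx = _numeric(df, "stimulus_index", path)
    inten = _numeric(df, "intensity_mA", path)
    amp = _numeric(df, "amplitude_mV", path)
    return CMAPScan(idx.astype(int), inten, amp)


def write_scan(scan: CMAPScan, path) -> None:
    df = pd.DataFrame({
        "stimulus_index": scan.stimulus_index,
        "intensity_mA": scan.intensity,
        "amplitude_mV": scan.amplitude,
    })
    df.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path) -> CohortTable:
    """Read a cohort TSV.  Clinical columns are optional (controls have no
    published per-subject data); unknown columns are preserved and flagged
    later by the analysis stage."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ScanParseError(f"{path}: file is empty") from None
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ScanParseError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ScanParseError(f"{path}: no subject rows")
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            _numeric(df, col, path)
    return CohortTable(df)


def write_cohort(table: CohortTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_table1_fixture() -> CohortTable:
    """The packaged 13-row SCI per-subject table (clinical scores, MUNE,
    maximum CMAP and D50 for each tetraplegic subject)."""
    with resources.as_file(
        resources.files("cmapscan.data") / "table1_sci_cohort.tsv"
    ) as p:
        return read_cohort(p)


@dataclass
class RunConfig:
    """End-to-end run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    n_stimuli: int = 500
    n_per_group: int = 13
    alpha: float = 0.05
    fit_runs: int = 3
    fit_error_threshold: float = 7.0
    fit_max_iterations: int = 1500
    fit_replicates: int = 12
    fit_max_batches: int = 5
    out_dir: str = "cmapscan_run"
    verbosity: int = 1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
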