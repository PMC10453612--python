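"""Readers and writers for the pipeline's plain-text and image formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ParameterError


def read_dose_table(path) -> pd.DataFrame:
    """Dose-response CSV: columns dose, modulator_level, growth_pct, replicate."""
    table = pd.read_csv(path)
    required = {"dose", "growth_pct"}
    if not required.issubset(table.columns):
        raise ParameterError(f"dose table must have columns {sorted(required)}")
    if "modulator_level" not in table.columns:
        table["modulator_level"] = 0.0
    if "replicate" not in table.columns:
        table["replicate"] = 0
    return table


def write_dose_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_events(path) -> np.ndarray:
    """DNA-content event list: one intensity per row (header optional)."""
    series = pd.read_csv(path).squeeze("columns")
    return np.asarray(series, dtype=float).ravel()


def write_events(events, path) -> None:
    pd.DataFrame({"intensity": np.asarray(events)}).to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix from TSV (first column = gene id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise ParameterError("count matrix has negative entries")
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    """Sample design TSV: columns sample, condition, replicate."""
    design = pd.read_csv(path, sep="\t")
    if "sample" in design.columns:
        design = design.set_index("sample")
    if "condition" not in design.columns:
        raise ParameterError("design table needs a 'condition' column")
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t")


def write_field(nuclear: np.ndarray, reporter: np.ndarray, path) -> None:
    """Two-channel 16-bit TIFF, nuclear channel first."""
    tifffile.imwrite(path, np.stack([nuclear, reporter]).astype(np.uint16))


def read_field(path) -> tuple[np.ndarray, np.ndarray]:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ParameterError("expected a two-channel image stack")
    return stack[0], stack[1]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serialisable: {type(value)}")
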