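"""Trial-table file format and run configuration.

Trial tables are plain CSV (UTF-8, comma separator, '.' decimal) with a
header naming stimulus columns ``s1..sk`` and response columns ``r1..rm``
(``m = 1`` for scalar responses); an optional leading ``trial`` index column
is ignored on read.  Responses parse canonically: integer-valued columns
become integers, other values strings; tables round-trip losslessly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Any, Dict, List, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .engine import TrialData

__all__ = ["RunConfig", "TrialFormatError", "read_trials", "write_trials"]


class TrialFormatError(ValueError):
    """Raised for malformed trial tables, with row/column context."""


def write_trials(data: TrialData, path) -> None:
    """Write a :class:`TrialData` to CSV with ``s1..sk`` / ``r1..rm`` columns."""
    stim = np.asarray(data.stimuli)
    if stim.ndim == 1:
        stim = stim[:, None]
    resp = np.asarray(data.responses)
    if resp.ndim == 1:
        resp = resp[:, None]
    frame = pd.DataFrame({"trial": np.arange(stim.shape[0])})
    for j in range(stim.shape[1]):
        frame[f"s{j + 1}"] = stim[:, j]
    for j in range(resp.shape[1]):
        frame[f"r{j + 1}"] = resp[:, j]
    frame.to_csv(path, index=False)


def _ordered_columns(columns, prefix: str) -> List[str]:
    pat = re.compile(rf"^{prefix}(\d+)$")
    found = sorted(
        (int(m.group(1)), c) for c in columns if (m := pat.match(c))
    )
    names = [c for _, c in found]
    if [i for i, _ in found] != list(range(1, len(found) + 1)):
        raise TrialFormatError(
            f"{prefix}-columns must be numbered consecutively from "
            f"{prefix}1, got {names}"
        )
    return names


def read_trials(path) -> TrialData:
    """Read a trial table CSV into :class:`TrialData`.

    Ragged rows and missing response columns raise :class:`TrialFormatError`
    with as much location context as the parser provides.
    """
    try:
        frame = pd.read_csv(path, sep=",", decimal=".", encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise TrialFormatError(f"malformed trial table {path}: {exc}") from exc
    if frame.empty:
        raise TrialFormatError(f"trial table {path} contains no rows")

    s_cols = _ordered_columns(frame.columns, "s")
    r_cols = _ordered_columns(frame.columns, "r")
    if not r_cols:
        raise TrialFormatError(f"trial table {path} has no response column r1")
    if not s_cols:
        raise TrialFormatError(f"trial table {path} has no stimulus column s1")

    for col in r_cols:
        bad = frame[col].isna()
        if bad.any():
            lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # header = line 1
            raise TrialFormatError(
                f"missing response values in column {col} at line(s) {lines[:5]}"
            )

    stimuli = frame[s_cols].to_numpy(dtype=float)
    if stimuli.shape[1] == 1:
        stimuli = stimuli[:, 0]

    resp_frame = frame[r_cols].apply(_canonical_column)
    responses = resp_frame.to_numpy()
    if responses.shape[1] == 1:
        responses = responses[:, 0]
    else:
        responses = np.array([tuple(row) for row in responses], dtype=object)
    return TrialData(stimuli=stimuli, responses=responses)


def _canonical_column(col: pd.Series) -> pd.Series:
    """Integers as integers, everything else as strings (or floats)."""
    if pd.api.types.is_integer_dtype(col):
        return col.astype(np.int64)
    if pd.api.types.is_float_dtype(col):
        if np.all(np.mod(col.to_numpy(), 1) == 0):
            return col.astype(np.int64)
        return col
    return col.astype(str)


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    model: str
    params: Dict[str, float]
    arm: Literal["ibs", "fixed", "exact"] = "ibs"
    repeats: int = Field(default=1, ge=1)
    n_samples: int = Field(default=10, ge=1)
    bounds: Optional[Dict[str, List[float]]] = None
    seed: int = Field(default=0, ge=0)
    output: Optional[str] = None
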