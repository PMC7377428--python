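"""Reading, writing and validation of the delimited data tables.

All interchange is comma-separated UTF-8 text with one header row and "."
decimals.  RTs are stored in seconds; files recorded in milliseconds are
converted on read via ``units="ms"``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .task import STIMULUS_IDS

__all__ = [
    "TRIALS_COLUMNS",
    "split_pair",
    "pair_key",
    "read_trials",
    "write_trials",
    "read_subjects",
    "write_subjects",
]

TRIALS_COLUMNS = [
    "subject_id",
    "block",
    "block_type",
    "trial",
    "pair",
    "left_stim",
    "choice",
    "rt_s",
    "outcome",
    "counterfactual",
    "satisfaction",
]

_FLOAT_FORMAT = "%.10g"  # fixed formatting keeps seeded runs byte-identical


def pair_key(a: str, b: str) -> str:
    """Canonical pair string: members sorted lexicographically, '-'-joined."""
    lo, hi = sorted((a, b))
    return f"{lo}-{hi}"


def split_pair(pair: str) -> Tuple[str, str]:
    """Inverse of :func:`pair_key`."""
    first, sep, second = pair.partition("-")
    if not sep or not first or not second:
        raise ValueError(f"malformed pair string {pair!r}")
    return first, second


class SchemaError(ValueError):
    """A trials table violated the documented schema."""


def read_trials(path, units: str = "s") -> pd.DataFrame:
    """Read and validate a trials table.

    Parameters
    ----------
    path
        CSV file with the columns in :data:`TRIALS_COLUMNS`.
    units
        ``"s"`` (default) or ``"ms"``; millisecond RTs are divided by 1000.

    Raises
    ------
    SchemaError
        On missing columns, non-numeric RTs, or a choice outside its pair;
        messages name the offending (1-based, header-exclusive) row.
    """
    if units not in ("s", "ms"):
        raise ValueError(f"units must be 's' or 'ms', got {units!r}")
    df = pd.read_csv(path)
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[TRIALS_COLUMNS].copy()

    rt = pd.to_numeric(df["rt_s"], errors="coerce")
    bad = np.flatnonzero(rt.isna() | (rt <= 0))
    if bad.size:
        raise SchemaError(f"{path}: non-numeric or non-positive rt on row {bad[0] + 1}")
    df["rt_s"] = rt / 1000.0 if units == "ms" else rt

    for i, (pair, choice) in enumerate(zip(df["pair"], df["choice"]), start=1):
        members = split_pair(str(pair))
        if choice not in members:
            raise SchemaError(f"{path}: choice {choice!r} not in pair {pair!r} on row {i}")
        for stim in members:
            if stim not in STIMULUS_IDS:
                raise SchemaError(f"{path}: unknown stimulus {stim!r} on row {i}")
    df["counterfactual"] = pd.to_numeric(df["counterfactual"], errors="coerce")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"refusing to write trials table lacking {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[TRIALS_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "stai_t" not in df.columns:
        raise SchemaError(f"{path}: subjects table needs subject_id and stai_t columns")
    return df


def write_subjects(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path) -> None:
    """Generic table writer with the project's fixed float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
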