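"""Tidy CSV interchange formats.

All files are UTF-8, '.'-decimal CSV with fixed headers; time is in hours
and the time axis starts at the treatment instant t = 0.  Impedance is
stored long: one row per (well, time, frequency).  Undefined alpha/Cm cells
are written empty, never as 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IMPEDANCE_COLUMNS",
    "FIT_COLUMNS",
    "read_impedance_csv",
    "write_impedance_csv",
    "read_reference_csv",
    "write_reference_csv",
    "write_fits_csv",
    "read_fits_csv",
    "write_table",
]

IMPEDANCE_COLUMNS = ["well", "group", "time_h", "frequency_hz",
                     "z_real_ohm", "z_imag_ohm"]
REFERENCE_COLUMNS = ["frequency_hz", "z_real_ohm", "z_imag_ohm"]
FIT_COLUMNS = ["well", "group", "time_h", "rb_ohm_cm2", "alpha_ohm05_cm",
               "cm_uf_cm2", "rss", "flag"]


class FormatError(ValueError):
    """Raised on schema violations in interchange files."""


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: header must be exactly {expected}, got {list(df.columns)}"
        )


def write_impedance_csv(df: pd.DataFrame, path) -> None:
    _require_columns(df[IMPEDANCE_COLUMNS], IMPEDANCE_COLUMNS, path)
    df[IMPEDANCE_COLUMNS].to_csv(path, index=False)


def read_impedance_csv(path) -> pd.DataFrame:
    """Read and validate a long-format impedance table.

    Validates the header, per-well time monotonicity and frequency-grid
    consistency across wells; failures name the offending well.
    """
    df = pd.read_csv(path)
    _require_columns(df, IMPEDANCE_COLUMNS, path)
    grids = {}
    for well, sub in df.groupby("well", sort=False):
        times = sub["time_h"].unique()
        if np.any(np.diff(times) <= 0):
            raise FormatError(f"{path}: non-monotone time for well {well}")
        grid = tuple(sorted(sub["frequency_hz"].unique()))
        grids[well] = grid
    if len(set(grids.values())) > 1:
        raise FormatError(f"{path}: wells carry mixed frequency grids")
    return df


def write_reference_csv(df: pd.DataFrame, path) -> None:
    df[REFERENCE_COLUMNS].to_csv(path, index=False)


def read_reference_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, REFERENCE_COLUMNS, path)
    if np.any(np.diff(df["frequency_hz"]) <= 0):
        raise FormatError(f"{path}: reference frequencies must ascend")
    return df


def write_fits_csv(df: pd.DataFrame, path) -> None:
    """Write per-time-point fits; NaN alpha/Cm become empty cells."""
    _require_columns(df[FIT_COLUMNS], FIT_COLUMNS, path)
    df[FIT_COLUMNS].to_csv(path, index=False, na_rep="")


def read_fits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, FIT_COLUMNS, path)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Generic results table (summaries, comparisons, LDH) with empty NaNs."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")
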