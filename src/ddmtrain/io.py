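"""Delimited-text I/O for trial tables and derived artifacts.

One flat comma-delimited trial format with a fixed header::

    participant,session,task,trial,is_match,response,correct,rt_ms

RTs are milliseconds by default; a ``rt_s`` column (seconds) is accepted
and converted on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "write_table"]

REQUIRED = ["participant", "session", "task", "trial", "correct"]
_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _parse_bool(series: pd.Series, name: str, path) -> pd.Series:
    s = series.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if s.isna().any():
        line = int(series.index[s.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: unparseable {name!r} value at line {line}")
    return s.astype(bool)


def read_trials(path, rt_unit: str = "ms") -> pd.DataFrame:
    """Read a delimited trial table into the canonical DataFrame.

    Raises with the offending line number for missing columns,
    unparseable fields, or non-positive RTs. An empty file with a valid
    header yields an empty table.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "rt_ms" not in df.columns and "rt_s" not in df.columns:
        raise ValueError(f"{path}: missing RT column ('rt_ms' or 'rt_s')")

    if len(df) == 0:
        out = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            TRIAL_COLUMNS, [str, int, str, int, bool, str, bool, float])})
        return out

    out = pd.DataFrame()
    out["participant"] = df["participant"].astype(str)
    for col in ("session", "trial"):
        num = pd.to_numeric(df[col], errors="coerce")
        if num.isna().any():
            line = int(df.index[num.isna()][0]) + 2
            raise ValueError(f"{path}: unparseable {col!r} value at line {line}")
        out[col] = num.astype(int)
    out["task"] = df["task"].astype(str)
    out["correct"] = _parse_bool(df["correct"], "correct", path)
    out["is_match"] = (
        _parse_bool(df["is_match"], "is_match", path) if "is_match" in df.columns else False
    )
    out["response"] = df["response"].astype(str) if "response" in df.columns else ""

    rt_col = "rt_ms" if "rt_ms" in df.columns else "rt_s"
    rt = pd.to_numeric(df[rt_col], errors="coerce")
    if rt.isna().any():
        line = int(df.index[rt.isna()][0]) + 2
        raise ValueError(f"{path}: unparseable RT value at line {line}")
    rt_ms = rt if rt_col == "rt_ms" else rt * 1000.0
    if rt_unit == "s" and rt_col == "rt_ms":
        rt_ms = rt * 1000.0  # caller declared seconds despite the ms header name
    if (rt_ms <= 0).any():
        line = int(df.index[rt_ms <= 0][0]) + 2
        raise ValueError(f"{path}: non-positive RT at line {line}")
    out["rt_ms"] = rt_ms.astype(float)
    return out[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the canonical trial table as comma-delimited text."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write any derived table (fits, PPC, comparisons, ANOVA) as CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
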