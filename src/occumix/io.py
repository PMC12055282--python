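"""Reading and writing delimited event tables.

The on-disk format is a UTF-8, comma-delimited table with a header row and
one row per event x behaviour x observation window:

    individual_id,site,activity,period,duration_s,behaviour,occurred[,event_id]

``activity`` is one of drum / stone_and_drum / stone, ``period`` one of
before / after (combined rows are produced by the pipeline, not read),
``occurred`` is 0/1 and ``duration_s`` an integer >= 1.  ``event_id`` is
optional and pairs the before/after windows of one signalling event.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .data import ACTIVITIES, BEHAVIOURS, REQUIRED_COLUMNS, Dataset

__all__ = ["read_events", "write_events"]

_READ_PERIODS = ("before", "after", "combined")


def read_events(path) -> Dataset:
    """Read and validate an event table.

    Rows violating the schema are reported with their file line numbers
    (header = line 1).  Counts per (behaviour, period, activity) are stored
    in ``Dataset.metadata['counts']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header is missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    problems: list[str] = []

    def complain(mask, message):
        lines = (df.index[mask] + 2).tolist()  # +1 header, +1 zero-based
        if lines:
            problems.append(f"{message} on line(s) {lines[:20]}")

    for col, allowed in (
        ("activity", ACTIVITIES),
        ("period", _READ_PERIODS),
        ("behaviour", BEHAVIOURS),
    ):
        bad_mask = ~df[col].isin(allowed)
        if bad_mask.any():
            bad_values = sorted(set(df.loc[bad_mask, col].astype(str)))
            complain(bad_mask, f"unknown {col} value(s) {bad_values}")

    complain(~df["occurred"].isin(["0", "1"]), "occurred must be 0 or 1")
    dur = pd.to_numeric(df["duration_s"], errors="coerce")
    complain(dur.isna() | (dur < 1), "duration_s must be a number >= 1")
    complain(df[list(REQUIRED_COLUMNS)].isna().any(axis=1), "missing value in a model column")

    if problems:
        raise ValueError(f"{path}: invalid event table:\n  " + "\n  ".join(problems))

    df["occurred"] = df["occurred"].astype(int)
    df["duration_s"] = dur
    dataset = Dataset(df, metadata={"source": str(path)})
    counts = (
        df.groupby(["behaviour", "period", "activity"], sort=True).size().rename("n").reset_index()
    )
    dataset.metadata["counts"] = counts
    return dataset


def write_events(data: Dataset, path) -> Path:
    """Write an event table in the same format ``read_events`` accepts."""
    path = Path(path)
    cols = list(REQUIRED_COLUMNS) + (["event_id"] if "event_id" in data.df.columns else [])
    out = data.df[cols].copy()
    out["duration_s"] = out["duration_s"].astype(float).map(
        lambda v: int(v) if float(v).is_integer() else v
    )
    out.to_csv(path, index=False)
    return path
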