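"""Reading and writing the three registry tables.

Tables round-trip losslessly through either delimited text (CSV) or columnar
(Parquet) files; nullable integer columns (death/emigration dates) use
pandas' Int64 dtype so missing months survive the round trip.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

__all__ = ["write_registry", "read_registry", "TABLE_NAMES"]

TABLE_NAMES = ("persons", "dispensings", "fractures")

_PERSON_INT64 = ["death_year", "death_month", "emig_year", "emig_month"]


def _coerce(persons: pd.DataFrame, dispensings: pd.DataFrame, fractures: pd.DataFrame):
    persons = persons.copy()
    for c in _PERSON_INT64:
        if c in persons:
            persons[c] = persons[c].astype("Int64")
    fractures = fractures.copy()
    if "is_history" in fractures:
        fractures["is_history"] = fractures["is_history"].astype(bool)
    return persons, dispensings, fractures


def write_registry(tables, path, fmt: str = "csv") -> list[Path]:
    """Write (persons, dispensings, fractures) under ``path``.

    ``fmt`` is 'csv' or 'parquet'.  Returns the written file paths.
    """
    if fmt not in ("csv", "parquet"):
        raise ValueError(f"unknown format: {fmt!r}")
    persons, dispensings, fractures = _coerce(*tables)
    path = Path(path)
    os.makedirs(path, exist_ok=True)
    written = []
    for name, frame in zip(TABLE_NAMES, (persons, dispensings, fractures)):
        target = path / f"{name}.{fmt}"
        if fmt == "csv":
            frame.to_csv(target, index=False)
        else:
            frame.to_parquet(target, index=False)
        written.append(target)
    return written


def read_registry(path, fmt: str = "csv"):
    """Read (persons, dispensings, fractures) written by :func:`write_registry`."""
    if fmt not in ("csv", "parquet"):
        raise ValueError(f"unknown format: {fmt!r}")
    path = Path(path)
    frames = []
    for name in TABLE_NAMES:
        target = path / f"{name}.{fmt}"
        if fmt == "csv":
            frame = pd.read_csv(target)
        else:
            frame = pd.read_parquet(target)
        frames.append(frame)
    persons, dispensings, fractures = frames
    if len(fractures) == 0:
        fractures = fractures.astype(
            {"person_id": "int64", "year": "int64", "month": "int64", "is_history": bool},
            errors="ignore",
        )
    return _coerce(persons, dispensings, fractures)
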