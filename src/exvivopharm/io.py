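"""Delimited-table reading and writing with schema checks.

All pipeline artifacts are comma-separated, header-row, UTF-8 tables.
Headers are matched order-insensitively against the expected schema and
errors name the offending file and columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["TableError", "read_table", "write_table"]


class TableError(ValueError):
    """Raised for missing files, wrong headers or unparseable tables."""


def read_table(path, schema: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking that every schema column is present.

    Column order in the file is irrelevant; extra columns are kept.
    """
    path = Path(path)
    if not path.exists():
        raise TableError(f"table not found: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise TableError(f"cannot parse {path}: {exc}") from exc
    if schema:
        missing = [c for c in schema if c not in frame.columns]
        if missing:
            hint = ""
            if len(frame.columns) == 1 and any(c in str(frame.columns[0]) for c in schema):
                hint = " (wrong delimiter? expected comma-separated)"
            raise TableError(f"{path}: missing columns {missing}{hint}")
    return frame


def write_table(frame: pd.DataFrame, path) -> Path:
    """Write a CSV table at full float precision (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
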