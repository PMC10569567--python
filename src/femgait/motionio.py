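"""Reading and writing motion tables.

Two dialects: ``sto_mot`` — the tab-delimited motion-text dialect with a
header block ending in ``endheader`` and ``nRows`` / ``nColumns`` counts —
and plain ``csv``.  Values survive a write/read round trip to 1e-12 and
column names exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

DIALECTS = ("sto_mot", "csv")


def write_motion(path: str | Path, table: pd.DataFrame,
                 dialect: str = "sto_mot", name: str | None = None) -> None:
    """Write a motion table; first column is conventionally ``time``."""
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if dialect == "csv":
        table.to_csv(path, index=False, float_format="%.17g")
        return
    lines = [name or path.stem,
             "version=1",
             f"nRows={len(table)}",
             f"nColumns={len(table.columns)}",
             "inDegrees=yes",
             "endheader",
             "\t".join(str(c) for c in table.columns)]
    for row in table.itertuples(index=False):
        lines.append("\t".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_motion(path: str | Path, dialect: str = "sto_mot") -> pd.DataFrame:
    """Read a motion table, validating the declared dialect."""
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if dialect == "csv":
        return pd.read_csv(path)
    lines = path.read_text().splitlines()
    meta = {}
    header_end = None
    for i, line in enumerate(lines):
        if line.strip() == "endheader":
            header_end = i
            break
        if "=" in line:
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    if header_end is None:
        raise FormatError("no 'endheader' line found")
    try:
        n_rows = int(meta["nRows"])
        n_cols = int(meta["nColumns"])
    except (KeyError, ValueError) as e:
        raise FormatError(f"missing or malformed nRows/nColumns: {e}") from e
    if header_end + 1 >= len(lines):
        raise FormatError("missing column-name line", line=header_end + 2)
    columns = lines[header_end + 1].split("\t")
    if len(columns) != n_cols:
        raise FormatError(
            f"header declares {n_cols} columns but found {len(columns)}",
            line=header_end + 2)
    body = [ln for ln in lines[header_end + 2:] if ln.strip()]
    if len(body) != n_rows:
        raise FormatError(
            f"header declares {n_rows} rows but found {len(body)}",
            line=header_end + 3)
    data = np.empty((n_rows, n_cols))
    for r, ln in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise FormatError(
                f"row has {len(parts)} fields, expected {n_cols}",
                line=header_end + 3 + r)
        try:
            data[r] = [float(p) for p in parts]
        except ValueError as e:
            raise FormatError(f"non-numeric value: {e}",
                              line=header_end + 3 + r) from e
    return pd.DataFrame(data, columns=columns)
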