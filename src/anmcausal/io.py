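"""File ingest and egress: pair tables, expression matrices, edge lists."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import PairedSample

__all__ = [
    "read_pair_table",
    "write_pair_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_reference_edges",
]

logger = logging.getLogger("anmcausal")

MIN_ROWS = 20


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_pair_table(
    path: str | Path,
    column_x: str | None = None,
    column_y: str | None = None,
) -> PairedSample:
    """Read a two-column numeric table (CSV or TSV, sniffed by extension).

    Rows with any missing or non-numeric entry are dropped (count
    logged).  Columns default to the first two in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if column_x is None:
        column_x = df.columns[0]
    if column_y is None:
        column_y = df.columns[1] if len(df.columns) > 1 else df.columns[0]
    for col in (column_x, column_y):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path.name}")
    pair = df[[column_x, column_y]].apply(pd.to_numeric, errors="coerce")
    n_before = len(pair)
    pair = pair.dropna()
    dropped = n_before - len(pair)
    if dropped:
        logger.warning("dropped %d incomplete rows from %s", dropped, path.name)
    if len(pair) < MIN_ROWS:
        raise ValueError(
            f"{path.name}: only {len(pair)} complete rows; need at least {MIN_ROWS}"
        )
    return PairedSample(
        pair[column_x].to_numpy(dtype=float),
        pair[column_y].to_numpy(dtype=float),
        labels=(str(column_x), str(column_y)),
    )


def write_pair_table(data: PairedSample, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({data.labels[0]: data.x, data.labels[1]: data.y}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV: first column gene id, header of sample ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    expr = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    expr = expr.apply(pd.to_numeric, errors="coerce")
    if expr.isna().any().any():
        raise ValueError(f"{path.name}: expression matrix has missing values")
    return expr


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(Path(path), sep="\t")


def read_reference_edges(path: str | Path) -> set[tuple[str, str]]:
    """Two-column TSV (source, target), one edge per line; '#' comments."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: set[tuple[str, str]] = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path.name}: malformed edge line {line!r}")
        src, tgt = parts[0].strip(), parts[1].strip()
        if src == tgt:
            raise ValueError(f"{path.name}: self-loop {src!r}")
        edges.add((src, tgt))
    return edges
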