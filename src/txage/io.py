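"""TSV and BED-like readers/writers shared by all stages.

Everything on disk is tab-separated text: matrices with a header row of
column labels and a first column of row labels, annotation intervals as
BED-like tables (chrom, start, end, name, optional class columns; 0-based
half-open coordinates), and '#'-prefixed metadata header lines. Readers
validate shape, label uniqueness and value ranges and point at the offending
row/column in error messages; every file the pipeline writes is re-readable
by these functions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("txage")

__all__ = ["read_matrix", "write_matrix", "read_bed_like", "write_bed_like"]

MATRIX_KINDS = ("expression", "methylation", "covariates", "phenotypes", "detection_p")


def read_matrix(path: str | Path, kind: str = "expression") -> pd.DataFrame:
    """Read a labelled TSV matrix or table.

    ``kind`` selects validation: ``methylation`` and ``detection_p`` values
    must lie in [0, 1]; ``expression``, ``methylation``, ``detection_p`` and
    ``phenotypes`` must be fully numeric; ``covariates`` may mix numeric and
    factor columns. Duplicate row or column labels are rejected.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; one of {MATRIX_KINDS}")
    path = Path(path)
    # pandas de-duplicates repeated header labels silently; check them raw
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ValueError(f"{path}: empty file")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise ValueError(f"{path}: duplicate column label {col!r}")
        seen.add(col)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed TSV ({e})") from None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row label {dup!r}")
    if kind != "covariates":
        bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
    if kind in ("methylation", "detection_p"):
        vals = df.to_numpy(dtype=float)
        out = (vals < 0) | (vals > 1)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValueError(
                f"{path}: value {vals[i, j]!r} outside [0, 1] at row "
                f"{df.index[i]!r}, column {df.columns[j]!r}"
            )
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a labelled TSV matrix with optional '#key=value' header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"#{key}={val}\n")
        df.to_csv(fh, sep="\t")


def read_bed_like(path: str | Path) -> pd.DataFrame:
    """Read a BED-like annotation table (0-based half-open intervals).

    Expects at least ``chrom, start, end, name``; extra class columns pass
    through. Intervals with ``end <= start`` are rejected; an unsorted file
    is sorted with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["chrom", "start", "end", "name"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df["end"] <= df["start"]
    if bad.any():
        i = df.index[bad][0]
        raise ValueError(
            f"{path}: interval with end <= start at row {i} "
            f"({df.loc[i, 'start']}..{df.loc[i, 'end']})"
        )
    sorted_df = df.sort_values(["chrom", "start", "end"], kind="stable")
    if not sorted_df.index.equals(df.index):
        logger.warning("%s: intervals were unsorted; sorted on read", path)
        df = sorted_df.reset_index(drop=True)
    return df


def write_bed_like(df: pd.DataFrame, path: str | Path) -> None:
    """Write a BED-like annotation table as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
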