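"""Plain-text serialization of Mueller matrices and decomposition records.

Two on-disk layouts are supported and auto-detected:

* grid — 4 lines of 4 whitespace-separated decimal fields;
* row — a one-line header followed by one 16-column row per matrix
  (``m11 ... m44``, row-major, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "write_matrix",
    "write_matrices",
    "read_matrix",
    "read_matrices",
    "ROW_HEADER",
]

ROW_HEADER = [f"m{i}{j}" for i in range(1, 5) for j in range(1, 5)]


def write_matrix(path, M, fmt: str = "grid") -> None:
    """Write one Mueller matrix as a 4x4 grid or a headed 16-column row."""
    M = np.asarray(M, dtype=float).reshape(4, 4)
    if fmt == "grid":
        np.savetxt(path, M, fmt="%.12g", delimiter="\t")
    elif fmt == "row":
        write_matrices(path, [M])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_matrices(path, matrices) -> None:
    """Write matrices as TSV rows (m11..m44) under a one-line header."""
    rows = np.asarray([np.asarray(M, dtype=float).reshape(16) for M in matrices])
    np.savetxt(
        path, rows, fmt="%.12g", delimiter="\t",
        header="\t".join(ROW_HEADER), comments="",
    )


def read_matrices(path) -> np.ndarray:
    """Read matrices from either layout; returns array of shape (n, 4, 4)."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty Mueller matrix file")
    first = lines[0].split()
    if first and first[0] == "m11":  # headed row layout
        data = np.loadtxt(lines[1:], ndmin=2)
        if data.shape[1] != 16:
            raise ValueError(f"{path}: expected 16 columns, got {data.shape[1]}")
        return data.reshape(-1, 4, 4)
    data = np.loadtxt(lines, ndmin=2)
    if data.shape == (4, 4):
        return data[None, :, :]
    if data.shape[1] == 16:  # headerless rows are tolerated on read
        return data.reshape(-1, 4, 4)
    raise ValueError(f"{path}: unrecognized Mueller matrix layout {data.shape}")


def read_matrix(path) -> np.ndarray:
    """Read a single Mueller matrix (either layout)."""
    mats = read_matrices(path)
    if mats.shape[0] != 1:
        raise ValueError(f"{path}: expected one matrix, found {mats.shape[0]}")
    return mats[0]


def dump_json(path, record: dict) -> None:
    """Write a flat JSON record, converting numpy scalars/arrays."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(record, indent=2, default=default) + "\n")
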