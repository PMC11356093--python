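"""Square binary lattices and their on-disk formats.

The embryo substrate is an N x N grid of cell types {0, 1}, indexed
``(row, col)`` from the top-left corner, 0-based.  Distances between lattice
positions are Euclidean on the integer coordinates.  Grids are serialized as
ASCII PBM (P1), plain whitespace-separated 0/1 text, or CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Grid", "TargetPattern", "read_grid", "write_grid"]


def _validate_cells(cells: np.ndarray) -> np.ndarray:
    cells = np.asarray(cells)
    if cells.ndim != 2 or cells.shape[0] != cells.shape[1]:
        raise ValueError(f"grid must be square, got shape {cells.shape}")
    if cells.shape[0] < 2:
        raise ValueError("grid side must be >= 2")
    if not np.isin(cells, (0, 1)).all():
        raise ValueError("grid values must be 0 or 1")
    return cells.astype(np.uint8)


@dataclass(frozen=True)
class Grid:
    """An N x N lattice of binary cell types."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", _validate_cells(self.cells))

    @property
    def n(self) -> int:
        return self.cells.shape[0]

    def copy(self) -> "Grid":
        return Grid(self.cells.copy())

    def type_counts(self) -> tuple[int, int]:
        """(number of 0-cells, number of 1-cells)."""
        ones = int(self.cells.sum())
        return self.cells.size - ones, ones

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return self.cells.shape == other.cells.shape and bool(
            (self.cells == other.cells).all()
        )

    def __hash__(self) -> int:  # frozen dataclass wants one; content hash
        return hash(self.cells.tobytes())


@dataclass(frozen=True)
class TargetPattern:
    """A named goal lattice the embryo is expected to reproduce."""

    name: str
    grid: Grid

    @property
    def n(self) -> int:
        return self.grid.n

    @property
    def cells(self) -> np.ndarray:
        return self.grid.cells


def write_grid(grid: Grid | TargetPattern, path: str | Path, fmt: str | None = None) -> None:
    """Write a grid to ``path`` as ASCII PBM P1 (default), 0/1 text, or CSV.

    The format is inferred from the suffix (.pbm / .txt / .csv) unless ``fmt``
    is given explicitly.
    """
    if isinstance(grid, TargetPattern):
        grid = grid.grid
    path = Path(path)
    fmt = fmt or {".pbm": "pbm", ".csv": "csv"}.get(path.suffix.lower(), "txt")
    rows = [" ".join(str(int(v)) for v in row) for row in grid.cells]
    if fmt == "pbm":
        text = "P1\n{0} {0}\n".format(grid.n) + "\n".join(rows) + "\n"
    elif fmt == "csv":
        text = "\n".join(",".join(str(int(v)) for v in row) for row in grid.cells) + "\n"
    elif fmt == "txt":
        text = "\n".join(rows) + "\n"
    else:
        raise ValueError(f"unknown grid format {fmt!r}")
    path.write_text(text)


def read_grid(path: str | Path) -> Grid:
    """Read a grid from ASCII PBM (P1), plain 0/1 text, or CSV.

    Raises ``ValueError`` on non-binary values, ragged rows, or a PBM whose
    declared dimensions disagree with its bit content.
    """
    text = Path(path).read_text()
    tokens_by_line = [
        ln.replace(",", " ").split()
        for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if tokens_by_line and tokens_by_line[0][:1] == ["P1"]:
        flat = [t for ln in tokens_by_line for t in ln][1:]
        if len(flat) < 2:
            raise ValueError("truncated PBM header")
        w, h = int(flat[0]), int(flat[1])
        bits = flat[2:]
        if len(bits) != w * h:
            raise ValueError(f"PBM declares {w}x{h} but carries {len(bits)} bits")
        if w != h:
            raise ValueError("grid must be square")
        values = np.array([int(b) for b in bits], dtype=np.int64).reshape(h, w)
    else:
        widths = {len(ln) for ln in tokens_by_line}
        if len(widths) != 1:
            raise ValueError("ragged rows in grid file")
        values = np.array([[int(t) for t in ln] for ln in tokens_by_line], dtype=np.int64)
    return Grid(values)
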