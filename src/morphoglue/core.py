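"""Positional stress and the fitness of an embryo against its target.

A cell is *stressed* when its type differs from the target's type at that
position; otherwise it is *fixed*.  The stress map carries this intrinsic
binary field plus a temporary *shared* overlay written by blocked movers
during development (sharing mode only).

Fitness derives from the normalized l2 distance between embryo E and target T,

    d = (1/N^2) * sqrt( sum_ij (E_ij - T_ij)^2 )  =  sqrt(m) / N^2

for binary grids with m mismatches.  The closeness f = 1 - d is exponentiated
as f_exp = 9^f / 9, which expands resolution near the optimum: f_exp = 1.0
exactly at a perfect match and 1/9 at f = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import Grid, TargetPattern

__all__ = ["StressMap", "FitnessResult", "compute_stress_map", "l2_distance", "fitness"]


def _cells(g: Grid | TargetPattern | np.ndarray) -> np.ndarray:
    if isinstance(g, (Grid, TargetPattern)):
        return g.cells
    return np.asarray(g)


def _check_same_size(e: np.ndarray, t: np.ndarray) -> None:
    if e.shape != t.shape:
        raise ValueError(f"embryo {e.shape} and target {t.shape} differ in size")


@dataclass
class StressMap:
    """Binary intrinsic stress plus a temporary shared-stress overlay."""

    intrinsic: np.ndarray
    shared: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        """Elementwise OR of intrinsic and shared stress."""
        return (self.intrinsic | self.shared).astype(np.uint8)

    @property
    def n_stressed(self) -> int:
        """Number of intrinsically stressed cells."""
        return int(self.intrinsic.sum())

    def mean_combined(self) -> float:
        """Mean combined stress over all cells, in [0, 1]."""
        return float(self.combined.mean())

    def to_csv(self, path: str | Path) -> None:
        """Export with 0/1/2 coding: unstressed / intrinsic / shared-only."""
        coded = self.intrinsic.astype(np.uint8).copy()
        coded[(self.shared == 1) & (self.intrinsic == 0)] = 2
        text = "\n".join(",".join(str(int(v)) for v in row) for row in coded)
        Path(path).write_text(text + "\n")


@dataclass(frozen=True)
class FitnessResult:
    """Distance and (exponentiated) closeness of an embryo to its target."""

    d: float
    f: float
    f_exp: float


def compute_stress_map(embryo: Grid | np.ndarray, target: TargetPattern | np.ndarray) -> StressMap:
    """Elementwise mismatch indicator between embryo and target.

    The shared overlay starts all-zero; the development engine writes into it
    when blocked movers share stress.
    """
    e, t = _cells(embryo), _cells(target)
    _check_same_size(e, t)
    intrinsic = (e != t).astype(np.uint8)
    return StressMap(intrinsic=intrinsic, shared=np.zeros_like(intrinsic))


def l2_distance(embryo: Grid | np.ndarray, target: TargetPattern | np.ndarray) -> float:
    """Normalized l2 distance ``(1/N^2) * sqrt(sum (E-T)^2)``."""
    e, t = _cells(embryo), _cells(target)
    _check_same_size(e, t)
    diff = e.astype(np.int64) - t.astype(np.int64)
    return float(np.sqrt((diff * diff).sum()) / e.size)


def fitness(embryo: Grid | np.ndarray, target: TargetPattern | np.ndarray) -> FitnessResult:
    """Fitness of an embryo grid against a target pattern.

    Returns the raw distance ``d``, the closeness ``f = 1 - d``, and the
    exponentiated fitness ``f_exp = 9^f / 9`` (1.0 iff the grids match).
    """
    d = l2_distance(embryo, target)
    f = 1.0 - d
    return FitnessResult(d=d, f=f, f_exp=float(9.0**f / 9.0))
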