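"""Distress signaling between fixed cells and stressed movers.

Fixed cells (cells already at their correct position) watch their 3x3
neighborhood; on seeing a stressed neighbor they advertise a *vacancy* at the
stressed cell's location, broadcast to the whole grid as a radially decaying
signal with strength 1.0 at the origin.  The advertised location needs a
migrant carrying the target's type there, so only stressed cells of that type
receive the signal (and never the occupant itself).  Blocked movers may
*share* stress onto their 3x3 neighborhood, which is what later coerces fixed
cells into opening temporary tunnels.

Decay law: the signal is "radially diminishing" with origin strength 1.0; the
default form is ``strength(r) = 1/(1+r)`` on Euclidean r — positive, strictly
decreasing, never zero — so the strongest recorded signal is always the
nearest eligible vacancy.  Both the decay and the accumulation rule (max of
duplicate observations vs. their sum) are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .core import StressMap, compute_stress_map
from .grid import Grid, TargetPattern

__all__ = [
    "Vacancy",
    "DistressField",
    "DistressRecord",
    "default_decay",
    "emit_distress",
    "signal_strength",
    "collect_records",
    "share_stress",
]


def default_decay(r: float) -> float:
    """Default radial decay, 1/(1+r); 1.0 at the origin, never zero."""
    return 1.0 / (1.0 + r)


@dataclass(frozen=True)
class Vacancy:
    """An advertised stressed location and the cell type needed there.

    ``observers`` counts the fixed cells watching the location; it only
    matters under the summation accumulation rule.
    """

    location: tuple[int, int]
    required_type: int
    origin_strength: float = 1.0
    observers: int = 1


@dataclass
class DistressField:
    """All currently advertised vacancies plus the decay law in force."""

    vacancies: list[Vacancy]
    decay: Callable[[float], float] = default_decay

    def __len__(self) -> int:
        return len(self.vacancies)


@dataclass
class DistressRecord:
    """Signals accumulated by one stressed receiver, keyed by vacancy."""

    receiver: tuple[int, int]
    entries: dict[tuple[int, int], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def _cells(g) -> np.ndarray:
    return g.cells if isinstance(g, (Grid, TargetPattern)) else np.asarray(g)


def emit_distress(
    embryo: Grid | np.ndarray,
    target: TargetPattern | np.ndarray,
    stress: StressMap,
    decay: Callable[[float], float] = default_decay,
) -> DistressField:
    """One vacancy per stressed cell observed by at least one fixed 3x3 neighbor.

    Multiple fixed observers of the same stressed cell are de-duplicated into a
    single vacancy (duplicates would only rescale identical orderings).  The
    required type of a vacancy is the target's value at that location.
    """
    t = _cells(target)
    stressed = stress.intrinsic.astype(bool)
    fixed = ~stressed
    # A stressed cell is advertised iff some 8-neighbor is fixed.
    padded = np.pad(fixed, 1, constant_values=False)
    n_observers = np.zeros(stressed.shape, dtype=np.int64)
    n = stressed.shape[0]
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            if dr == 1 and dc == 1:
                continue
            n_observers += padded[dr : dr + n, dc : dc + n]
    vacancies = [
        Vacancy(
            location=(int(r), int(c)),
            required_type=int(t[r, c]),
            observers=int(n_observers[r, c]),
        )
        for r, c in np.argwhere(stressed & (n_observers > 0))
    ]
    return DistressField(vacancies=vacancies, decay=decay)


def signal_strength(
    field: DistressField, vacancy: Vacancy, at: tuple[int, int]
) -> float:
    """Strength of a vacancy's signal received at ``at`` under the field's decay."""
    r = float(np.hypot(at[0] - vacancy.location[0], at[1] - vacancy.location[1]))
    return vacancy.origin_strength * field.decay(r)


def collect_records(
    embryo: Grid | np.ndarray,
    target: TargetPattern | np.ndarray,
    stress: StressMap,
    field: DistressField,
    accumulate: str = "max",
) -> list[DistressRecord]:
    """Distress records of every eligible stressed receiver.

    A stressed cell receives a vacancy's signal iff its own cell value equals
    the vacancy's required type and it is not itself the vacancy's occupant.
    Under ``accumulate="max"`` (default) repeated observations of the same
    location collapse to one signal; under ``"sum"`` every fixed observer of
    the location contributes, so the recorded strength is the per-observer
    strength times the observer count.
    """
    if accumulate not in ("max", "sum"):
        raise ValueError(f"accumulate must be 'max' or 'sum', got {accumulate!r}")
    e = _cells(embryo)
    records: list[DistressRecord] = []
    for r, c in np.argwhere(stress.intrinsic.astype(bool)):
        rec = DistressRecord(receiver=(int(r), int(c)))
        for vac in field.vacancies:
            if vac.location == rec.receiver:
                continue  # self-exclusion: the occupant cannot fill its own spot
            if int(e[r, c]) != vac.required_type:
                continue
            s = signal_strength(field, vac, rec.receiver)
            if accumulate == "sum":
                s *= vac.observers
            rec.entries[vac.location] = s
        if rec.entries:
            records.append(rec)
    return records


def share_stress(stress: StressMap, blocked_mover: tuple[int, int]) -> StressMap:
    """Spread a blocked mover's stress onto its 3x3 neighborhood.

    Sets the shared overlay on the (border-clipped) neighborhood minus the
    mover's own cell — 8 positions for an interior mover, 3 at a corner; the
    intrinsic field is untouched.  Idempotent.  Raises if the mover is not
    intrinsically stressed.
    """
    r, c = blocked_mover
    if not stress.intrinsic[r, c]:
        raise ValueError(f"cell {blocked_mover} is not stressed; cannot share stress")
    n = stress.intrinsic.shape[0]
    r0, r1 = max(0, r - 1), min(n, r + 2)
    c0, c1 = max(0, c - 1), min(n, c + 2)
    center = stress.shared[r, c]
    stress.shared[r0:r1, c0:c1] = 1
    stress.shared[r, c] = center  # the mover itself is already intrinsically stressed
    return stress
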