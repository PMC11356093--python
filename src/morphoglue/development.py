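"""The developmental engine: iterated stress-relieving cell movement.

Each developmental *stage* resolves one movement: the stress map and distress
field are recomputed, a stressed cell with a nonempty distress record is
chosen uniformly at random, it picks the vacancy whose signal it receives most
strongly (ties broken at random), and it walks a greedy 8-connected shortest
path toward that destination, swapping with every non-fixed cell it meets.
What happens at a fixed cell depends on the embryo's mode:

* ``no_sharing`` — the mover halts where it stands (blocked) and *stays*
  stuck until some other cell dislodges it; a mover whose very first step is
  blocked cannot act at all.  Once no eligible mover can act, development is
  quiescent and ends — which is why developments without sharing are short.
* ``sharing`` — the mover shares its stress onto its 3x3 neighborhood,
  which opens a temporary tunnel: it passes through the fixed cell without
  displacing it (the fixed cell's value is identical before and after), at
  the usual cost of one swap per cell traversed.
* ``hardwired`` — no movement at all; the phenotype is the genotype.

Every swap (including tunnel passage) draws on a single embryo-global
competency budget; development ends when the target is formed, the budget is
exhausted, no mover can act, or a safety stage limit is hit.

The engine here is the implementation of record: pure numpy, one
:class:`MoveEvent` per stage with the full path, swap list, dislodgements and
tunnel cells, so any run can be replayed and audited.  The evolution driver
uses a compiled kernel with identical rules (see ``_kernel``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from .core import StressMap, fitness
from .grid import Grid, TargetPattern
from .signaling import DistressRecord, default_decay

__all__ = [
    "Mode",
    "Quiescence",
    "DevelopmentParams",
    "MoveEvent",
    "DevelopmentResult",
    "Development",
    "default_cap",
    "select_mover",
    "choose_destination",
    "develop",
]

Mode = Literal["sharing", "no_sharing", "hardwired"]

#: Fixed tie-break order for greedy steps: row steps, then column steps,
#: then diagonals.
_STEP_ORDER = ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1))


class Quiescence(Exception):
    """Raised when no eligible mover exists (development cannot proceed)."""


def default_cap(n: int) -> int:
    """Default competency cap for an ``n x n`` embryo: round(5.25 * n^2).

    Reproduces the reference value 4725 at n = 30 (2100 at n = 20); the
    quadratic scaling keeps the budget proportional to the number of cells.
    """
    return round(5.25 * n * n)


@dataclass
class DevelopmentParams:
    """Knobs of a single development run."""

    mode: Mode = "sharing"
    competency_cap: int | None = None  # None -> default_cap(N)
    seed: int = 0
    max_stages: int = 10_000
    decay: Callable[[float], float] = default_decay
    accumulate: str = "max"

    def cap_for(self, n: int) -> int:
        if self.mode == "hardwired":
            return 0
        return default_cap(n) if self.competency_cap is None else int(self.competency_cap)


@dataclass
class MoveEvent:
    """One resolved movement (one developmental stage)."""

    stage: int
    mover_origin: tuple[int, int]
    mover_final: tuple[int, int]
    destination: tuple[int, int]
    path: list[tuple[int, int]]
    swaps_used: int
    dislodged: list[tuple[tuple[int, int], tuple[int, int]]]  # (was-at, moved-to)
    tunneled: list[tuple[int, int]]
    blocked: bool
    truncated: bool = False
    swap_ops: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    shared: list[tuple[int, int]] = field(default_factory=list)

    @property
    def max_dislodge_radius(self) -> float:
        """Largest Euclidean distance from the move's start to a dislodged cell."""
        if not self.dislodged:
            return 0.0
        r0, c0 = self.mover_origin
        return max(math.hypot(r - r0, c - c0) for (r, c), _ in self.dislodged)

    @property
    def distance_moved(self) -> float:
        """Summed per-step Euclidean displacement of the mover along its path."""
        return sum(
            math.hypot(b[0] - a[0], b[1] - a[1])
            for a, b in zip(self.path, self.path[1:])
        )


@dataclass
class DevelopmentResult:
    """Phenotype plus the full audited trace of how it came about."""

    phenotype: Grid
    trace: list[MoveEvent]
    swaps_total: int
    distance_total: float
    stages: int
    stress_series: np.ndarray  # per-stage mean combined stress
    status: str  # completed | budget | quiescent | max_stages | hardwired
    params: DevelopmentParams
    genotype: Grid
    target: TargetPattern


def select_mover(
    stressed_cells: Sequence[tuple[int, int]], rng: np.random.Generator
) -> tuple[int, int]:
    """Uniform choice over the eligible stressed cells."""
    if len(stressed_cells) == 0:
        raise Quiescence("no eligible stressed cell to move")
    return tuple(stressed_cells[int(rng.integers(len(stressed_cells)))])


def choose_destination(
    record: DistressRecord, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Location of the strongest recorded signal; ties uniform; None if empty."""
    if not record.entries:
        return None  # mover idles this stage
    best = max(record.entries.values())
    winners = [loc for loc, s in record.entries.items() if s == best]
    return winners[int(rng.integers(len(winners)))]


def _greedy_step(
    cur: tuple[int, int], dest: tuple[int, int], n: int
) -> tuple[int, int]:
    """In-grid 8-neighbor of ``cur`` minimizing distance to ``dest``.

    Ties resolved by the fixed order row-step, column-step, diagonal.
    """
    best = None
    best_d2 = None
    for dr, dc in _STEP_ORDER:
        r, c = cur[0] + dr, cur[1] + dc
        if not (0 <= r < n and 0 <= c < n):
            continue
        d2 = (r - dest[0]) ** 2 + (c - dest[1]) ** 2
        if best_d2 is None or d2 < best_d2:
            best, best_d2 = (r, c), d2
    return best


class Development:
    """Stepping interface over one embryo's development.

    ``step()`` resolves one stage and returns its :class:`MoveEvent`, or
    ``None`` once development has terminated (``status`` says why).  The
    target may be replaced between stages (``retarget``), which is what the
    sequential-morphogenesis driver does.
    """

    def __init__(
        self,
        genome: Grid | np.ndarray,
        target: TargetPattern,
        params: DevelopmentParams | None = None,
    ):
        self.params = params or DevelopmentParams()
        genome_cells = genome.cells if isinstance(genome, Grid) else np.asarray(genome)
        if genome_cells.shape != target.cells.shape:
            raise ValueError(
                f"genome {genome_cells.shape} and target {target.cells.shape} differ in size"
            )
        self.genotype = Grid(genome_cells)
        self.target = target
        self.embryo = genome_cells.astype(np.uint8).copy()
        self.rng = np.random.default_rng(self.params.seed)
        self.cap = self.params.cap_for(target.n)
        self.swaps_total = 0
        self.distance_total = 0.0
        self.stages = 0
        self.trace: list[MoveEvent] = []
        self.stress_series: list[float] = []
        self.last_shared = np.zeros_like(self.embryo)
        # A mover whose move ends blocked stays stuck until another cell
        # dislodges it; only no_sharing moves can block.
        self.stuck = np.zeros(self.embryo.shape, dtype=bool)
        self.status: str | None = "hardwired" if self.params.mode == "hardwired" else None

    # -- state inspection ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.embryo.shape[0]

    def stress_map(self) -> StressMap:
        """Current stress map, shared overlay from the last resolved stage."""
        intrinsic = (self.embryo != self.target.cells).astype(np.uint8)
        return StressMap(intrinsic=intrinsic, shared=self.last_shared.copy())

    def mismatch_count(self) -> int:
        return int((self.embryo != self.target.cells).sum())

    def retarget(self, target: TargetPattern) -> None:
        if target.cells.shape != self.embryo.shape:
            raise ValueError("new target differs in size")
        self.target = target
        self.stuck[:] = False  # stuck-ness was relative to the old stress field
        if self.status in ("completed", "quiescent"):
            self.status = None  # a new target may re-enable movement

    # -- the stage loop -----------------------------------------------------
    def _vacancies(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(locations (k,2), required types (k,), observer counts (k,))."""
        t = self.target.cells
        stressed = self.embryo != t
        padded = np.pad(~stressed, 1, constant_values=False)
        n = self.n
        n_obs = np.zeros((n, n), dtype=np.int64)
        for dr in (0, 1, 2):
            for dc in (0, 1, 2):
                if dr == 1 and dc == 1:
                    continue
                n_obs += padded[dr : dr + n, dc : dc + n]
        locs = np.argwhere(stressed & (n_obs > 0))
        req = t[locs[:, 0], locs[:, 1]].astype(np.int64) if len(locs) else np.empty(0, int)
        obs = n_obs[locs[:, 0], locs[:, 1]] if len(locs) else np.empty(0, int)
        return locs, req, obs

    def _destination_for(
        self,
        mover: tuple[int, int],
        locs: np.ndarray,
        req: np.ndarray,
        obs: np.ndarray,
    ) -> tuple[int, int] | None:
        """Strongest-signal vacancy for this mover, ties uniform at random."""
        v = int(self.embryo[mover])
        mask = req == v
        if not mask.any():
            return None
        cand = locs[mask]
        d = np.hypot(cand[:, 0] - mover[0], cand[:, 1] - mover[1])
        strength = np.array([self.params.decay(x) for x in d])
        if self.params.accumulate == "sum":
            strength = strength * obs[mask]
        best = strength.max()
        winners = np.flatnonzero(strength == best)
        pick = winners[int(self.rng.integers(len(winners)))]
        return int(cand[pick, 0]), int(cand[pick, 1])

    def step_move(
        self, mover: tuple[int, int], destination: tuple[int, int]
    ) -> MoveEvent:
        """Execute one greedy shortest-path move; mutates the embryo grid."""
        if mover == destination:
            raise ValueError("destination equals mover position")
        if self.embryo[mover] == self.target.cells[mover]:
            raise ValueError(f"mover {mover} is not stressed")
        if self.swaps_total >= self.cap:
            raise ValueError("no competency budget remaining")
        t = self.target.cells
        n = self.n
        mode = self.params.mode
        cur = mover
        carrier = mover  # where the mover's value physically sits
        path = [mover]
        swap_ops: list[tuple[tuple[int, int], tuple[int, int]]] = []
        dislodged: list[tuple[tuple[int, int], tuple[int, int]]] = []
        tunneled: list[tuple[int, int]] = []
        shared: list[tuple[int, int]] = []
        overlay = np.zeros_like(self.embryo)
        blocked = truncated = False
        swaps = 0
        while cur != destination:
            if self.swaps_total + swaps >= self.cap:
                truncated = True
                break
            nxt = _greedy_step(cur, destination, n)
            if self.embryo[nxt] != t[nxt]:  # non-fixed: swap through
                self.embryo[carrier], self.embryo[nxt] = (
                    self.embryo[nxt],
                    self.embryo[carrier],
                )
                # a stuck marker travels with the displaced cell; the mover
                # itself is active by construction
                self.stuck[carrier] = self.stuck[nxt]
                self.stuck[nxt] = False
                swap_ops.append((carrier, nxt))
                dislodged.append((nxt, carrier))
                carrier = nxt
            else:  # fixed cell in the way
                if mode == "no_sharing":
                    blocked = True
                    break
                # sharing: spread stress around the mover, tunnel through
                r0, r1 = max(0, cur[0] - 1), min(n, cur[0] + 2)
                c0, c1 = max(0, cur[1] - 1), min(n, cur[1] + 2)
                for r in range(r0, r1):
                    for c in range(c0, c1):
                        if (r, c) != cur and not overlay[r, c]:
                            overlay[r, c] = 1
                            shared.append((r, c))
                tunneled.append(nxt)
            swaps += 1
            cur = nxt
            path.append(nxt)
        if blocked:
            self.stuck[carrier] = True  # stays stuck until dislodged
        # A mover stranded inside a tunnel settles back at its carrier cell.
        event = MoveEvent(
            stage=self.stages,
            mover_origin=mover,
            mover_final=carrier,
            destination=destination,
            path=path,
            swaps_used=swaps,
            dislodged=dislodged,
            tunneled=tunneled,
            blocked=blocked,
            truncated=truncated,
            swap_ops=swap_ops,
            shared=shared,
        )
        self.swaps_total += swaps
        self.distance_total += event.distance_moved
        self.last_shared = overlay
        return event

    def step(self) -> MoveEvent | None:
        """Resolve one developmental stage; ``None`` when development is over."""
        if self.status is not None:
            return None
        t = self.target.cells
        if self.mismatch_count() == 0:
            self.status = "completed"
            return None
        if self.swaps_total >= self.cap:
            self.status = "budget"
            return None
        if self.stages >= self.params.max_stages:
            self.status = "max_stages"
            return None
        locs, req, obs = self._vacancies()
        has_req = {v: bool((req == v).any()) for v in (0, 1)}
        stressed = np.argwhere(self.embryo != t)
        candidates = [
            (int(r), int(c))
            for r, c in stressed
            if has_req[int(self.embryo[r, c])] and not self.stuck[r, c]
        ]
        while candidates:
            mover = candidates.pop(int(self.rng.integers(len(candidates))))
            dest = self._destination_for(mover, locs, req, obs)
            if dest is None:
                continue
            if self.params.mode == "no_sharing":
                first = _greedy_step(mover, dest, self.n)
                if self.embryo[first] == t[first]:
                    self.stuck[mover] = True  # cannot take even one step
                    continue
            event = self.step_move(mover, dest)
            self.stages += 1
            self.trace.append(event)
            # Shared stress never outlives the move that created it, so the
            # combined field assessed after the stage equals the intrinsic one.
            self.stress_series.append(float((self.embryo != t).mean()))
            return event
        self.status = "quiescent"
        return None

    def run(self) -> DevelopmentResult:
        """Step until termination and package the result."""
        if self.params.mode != "hardwired":
            while self.step() is not None:
                pass
            if self.status is None and self.mismatch_count() == 0:
                self.status = "completed"
        return DevelopmentResult(
            phenotype=Grid(self.embryo.copy()),
            trace=self.trace,
            swaps_total=self.swaps_total,
            distance_total=self.distance_total,
            stages=self.stages,
            stress_series=np.asarray(self.stress_series, dtype=float),
            status=self.status or "completed",
            params=self.params,
            genotype=self.genotype,
            target=self.target,
        )


def develop(
    genome: Grid | np.ndarray,
    target: TargetPattern,
    params: DevelopmentParams | None = None,
) -> DevelopmentResult:
    """Run a full development of ``genome`` toward ``target``.

    Hardwired embryos return their genotype unchanged with an empty trace;
    competent embryos iterate stages until the target is formed, the
    competency budget is spent, or no mover can act.
    """
    return Development(genome, target, params).run()
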