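"""Observables of the developmental and evolutionary dynamics.

* radius of influence — per developmental stage, the maximum Euclidean
  distance between a mover's move-start position and any cell it dislodged
  that stage (the "cognitive light cone" proxy);
* stress-map gradient fields — the spatial derivative of the combined binary
  stress field, the view an external observer could draw;
* stress-map/target similarity — whether the stress field betrays the goal;
* sequential morphogenesis — development against a staged series of
  sub-targets, each introduced when mean stress stops decreasing;
* run aggregation — mean and t-based 95 % confidence band across replicate
  runs, and Welch's two-sample t-test between populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import StressMap, compute_stress_map
from .development import Development, DevelopmentParams, DevelopmentResult, MoveEvent
from .grid import Grid, TargetPattern
from .patterns import scramble

__all__ = [
    "GradientField",
    "StressTimeSeries",
    "ComparisonResult",
    "radius_of_influence",
    "stress_gradient",
    "similarity",
    "run_sequential",
    "aggregate_runs",
    "compare_populations",
]


# --------------------------------------------------------------------------
# radius of influence
# --------------------------------------------------------------------------

def radius_of_influence(trace: DevelopmentResult | list[MoveEvent]) -> np.ndarray:
    """Per-stage maximum dislodgement radius, in grid-cell units.

    Stages in which the mover dislodged nothing contribute 0.  A hardwired
    development has an empty trace, hence an empty (all-zero) series.
    """
    events = trace.trace if isinstance(trace, DevelopmentResult) else trace
    return np.asarray([ev.max_dislodge_radius for ev in events], dtype=float)


# --------------------------------------------------------------------------
# stress-map observables
# --------------------------------------------------------------------------

@dataclass
class GradientField:
    """Central-difference spatial gradient of the combined stress field."""

    d_row: np.ndarray
    d_col: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.d_row, self.d_col)

    def to_rows(self) -> list[tuple[int, int, float, float]]:
        """(row, col, g_row, g_col) tuples for CSV export."""
        n = self.d_row.shape[0]
        return [
            (r, c, float(self.d_row[r, c]), float(self.d_col[r, c]))
            for r in range(n)
            for c in range(n)
        ]


def stress_gradient(stress: StressMap) -> GradientField:
    """Gradient of the combined binary stress field (one-sided at borders)."""
    combined = stress.combined.astype(float)
    d_row, d_col = np.gradient(combined)
    return GradientField(d_row=d_row, d_col=d_col)


def similarity(
    stress: StressMap | np.ndarray,
    target: TargetPattern | np.ndarray,
    method: str = "squared",
) -> float:
    """Inverse l2 similarity between a binary stress field and the target.

    Default (``"squared"``): ``1 - sum((S - T)^2) / N^2`` — 1.0 on an exact
    match, 0.0 on the complement, and ~0.5 for a random balanced field.  The
    ``"rms"`` alternative ``1 - sqrt(sum((S - T)^2)) / N`` is available for
    comparison (it maps a random balanced field to ~0.29).
    """
    s = stress.combined if isinstance(stress, StressMap) else np.asarray(stress)
    t = target.cells if isinstance(target, TargetPattern) else np.asarray(target)
    if s.shape != t.shape:
        raise ValueError(f"stress field {s.shape} and target {t.shape} differ in size")
    sq = float(((s.astype(np.int64) - t.astype(np.int64)) ** 2).sum())
    if method == "squared":
        return 1.0 - sq / s.size
    if method == "rms":
        return 1.0 - math.sqrt(sq) / s.shape[0]
    raise ValueError(f"unknown similarity method {method!r}")


# --------------------------------------------------------------------------
# sequential morphogenesis
# --------------------------------------------------------------------------

@dataclass
class StressTimeSeries:
    """Per-stage mean stress of a sequential-subtarget development."""

    values: np.ndarray  # mean stress after each stage, vs the then-current target
    switch_stages: list[int]  # stage indices right after which the target changed
    swaps_total: int
    stages_total: int
    status: str  # status of the final phase
    target_names: list[str] = field(default_factory=list)

    @property
    def zero_step(self) -> int | None:
        """First stage (1-based) at which mean stress reached exactly zero."""
        hits = np.flatnonzero(self.values == 0.0)
        return int(hits[0]) + 1 if len(hits) else None

    @property
    def terminal_stress(self) -> float:
        return float(self.values[-1]) if len(self.values) else math.nan


def run_sequential(
    target_sequence: list[TargetPattern],
    mode: str,
    params: DevelopmentParams | None = None,
    initial: Grid | None = None,
) -> StressTimeSeries:
    """Develop against a staged series of sub-targets ending in the full pattern.

    The initial grid is a seeded scramble of the final pattern (so cell-type
    counts match the final target).  Development proceeds against the current
    sub-target; the next one is introduced at the first stage where mean
    stress fails to decrease (with a one-stage grace after each switch,
    because the switch itself raises stress by construction), or when the
    current phase goes quiescent.  One competency budget spans all phases.
    """
    if not target_sequence:
        raise ValueError("empty target sequence")
    params = params or DevelopmentParams()
    if params.mode != mode:
        params = DevelopmentParams(
            mode=mode,
            competency_cap=params.competency_cap,
            seed=params.seed,
            max_stages=params.max_stages,
            decay=params.decay,
            accumulate=params.accumulate,
        )
    final = target_sequence[-1]
    start = initial if initial is not None else scramble(final, params.seed)
    dev = Development(start, target_sequence[0], params)
    phase = 0
    values: list[float] = []
    switches: list[int] = []
    prev: float | None = None
    grace = 0

    def advance_phase() -> bool:
        """Switch to the next sub-target; False if already on the final one."""
        nonlocal phase, prev, grace
        if phase + 1 >= len(target_sequence):
            return False
        phase += 1
        dev.retarget(target_sequence[phase])
        switches.append(dev.stages)
        # stress re-read against the new target: the momentary rise
        prev = float((dev.embryo != dev.target.cells).mean())
        grace = 1
        return True

    while True:
        event = dev.step()
        if event is None:
            # completed / quiescent on this sub-target (or out of budget)
            if dev.status in ("budget", "max_stages"):
                break
            if not advance_phase():
                break
            continue
        value = dev.stress_series[-1]
        values.append(value)
        if prev is not None and grace == 0 and value >= prev:
            if not advance_phase():
                if value == 0.0:
                    break
                # final target: keep optimizing until a terminal condition
                prev = value
                continue
            continue
        if grace > 0:
            grace -= 1
        prev = value

    return StressTimeSeries(
        values=np.asarray(values, dtype=float),
        switch_stages=switches,
        swaps_total=dev.swaps_total,
        stages_total=dev.stages,
        status=dev.status or "completed",
        target_names=[t.name for t in target_sequence],
    )


# --------------------------------------------------------------------------
# run statistics
# --------------------------------------------------------------------------

def aggregate_runs(
    values: np.ndarray, confidence: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and t-based CI half-width per generation across runs.

    ``values`` has shape (runs, generations); at least two runs are required.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    r = values.shape[0]
    if r < 2:
        raise ValueError("need >= 2 runs to aggregate")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=r - 1)
    return mean, tcrit * sd / math.sqrt(r)


@dataclass(frozen=True)
class ComparisonResult:
    """Welch two-sample t-test between two populations' samples."""

    statistic: float
    pvalue: float
    degenerate: bool = False


def compare_populations(
    samples_a: np.ndarray, samples_b: np.ndarray
) -> ComparisonResult:
    """Welch's t-test (two-sided).  Zero-variance identical samples are flagged
    degenerate and reported as statistic 0, p = 1."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return ComparisonResult(statistic=0.0, pvalue=1.0, degenerate=True)
        return ComparisonResult(statistic=math.inf, pvalue=0.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(statistic=float(res.statistic), pvalue=float(res.pvalue))
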