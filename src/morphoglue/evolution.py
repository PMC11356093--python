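"""Genetic algorithm over developing embryos.

Each generation is the sequence development -> selection -> mutation:

1. every genome develops into a phenotype according to the population's
   reorganization mode (stress sharing, no sharing, or hardwired);
2. the genomes of the top ``selection_fraction`` of phenotypic fitnesses are
   selected (Darwinian selection on the phenotype, inheritance of the
   pre-development genotype), ties at the cutoff broken by stable population
   index;
3. the parents are retained unmutated (elitism) and the population is filled
   back to size M with mutated copies of uniformly drawn parents, a mutation
   being ``mutation_swaps`` random cell-pair swaps (cell-type counts are
   conserved forever).

Populations are homogeneous in mode.  Per generation the log records the
embryo with the best phenotypic fitness: its phenotypic and genotypic fitness
(both as raw distance d and as exponentiated fitness 9^(1-d)/9), the
competency (swaps) it used and the total Euclidean distance its cells moved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._kernel import develop_fast
from .development import DevelopmentParams, Mode, default_cap, develop
from .grid import Grid, TargetPattern
from .patterns import scramble

__all__ = [
    "Genome",
    "EvolutionConfig",
    "EvolutionLog",
    "init_population",
    "select",
    "mutate",
    "evolve",
]


@dataclass(frozen=True)
class Genome:
    """A heritable grid plus the reorganization gene marker."""

    grid: Grid
    mode_marker: Mode = "sharing"


@dataclass
class EvolutionConfig:
    """Parameters of one evolutionary experiment (possibly replicated)."""

    target: TargetPattern
    mode: Mode = "sharing"
    population_size: int = 100
    generations: int = 1000
    selection_fraction: float = 0.10
    mutation_swaps: int = 10
    competency_cap: int | None = None  # None -> default_cap(N)
    runs: int = 10
    base_seed: int = 0
    engine: Literal["fast", "reference"] = "fast"
    max_stages: int = 10_000

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must be in (0, 1]")
        if self.mutation_swaps < 0:
            raise ValueError("mutation_swaps must be >= 0")

    @property
    def cap(self) -> int:
        if self.mode == "hardwired":
            return 0
        return (
            default_cap(self.target.n)
            if self.competency_cap is None
            else int(self.competency_cap)
        )


@dataclass
class EvolutionLog:
    """Per-generation log rows for every replicate run, plus run seeds."""

    frame: pd.DataFrame
    config: EvolutionConfig
    run_seeds: list[int]

    def run(self, index: int) -> pd.DataFrame:
        return self.frame[self.frame["run"] == index].reset_index(drop=True)

    def at_generation(self, generation: int, column: str = "best_phen_fitness") -> np.ndarray:
        """One value per run at the given (1-based) generation."""
        sel = self.frame[self.frame["generation"] == generation]
        return sel.sort_values("run")[column].to_numpy()

    def first_generation_at_max(self) -> np.ndarray:
        """Per run, the first generation whose best phenotypic fitness is 1.0.

        Runs that never reach 1.0 report NaN.
        """
        out = []
        for run in sorted(self.frame["run"].unique()):
            rows = self.frame[self.frame["run"] == run]
            hit = rows[rows["best_phen_fitness"] >= 1.0]
            out.append(float(hit["generation"].iloc[0]) if len(hit) else math.nan)
        return np.asarray(out)


def init_population(
    target: TargetPattern, m: int, seed: int, mode: Mode = "sharing"
) -> list[Genome]:
    """M independent seeded scrambles of the target, sharing one mode marker."""
    if m < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=m)
    return [Genome(scramble(target, int(s)), mode) for s in seeds]


def select(
    population: Sequence[Genome],
    phenotypic_fitnesses: Sequence[float],
    fraction: float = 0.10,
) -> list[Genome]:
    """Top ``ceil(fraction * M)`` genomes by phenotypic fitness.

    Ties at the cutoff are broken by stable population index; the selected
    genomes are the pre-development genotypes.
    """
    if len(population) == 0:
        raise ValueError("empty population")
    if len(population) != len(phenotypic_fitnesses):
        raise ValueError("fitnesses not aligned with population")
    n_sel = math.ceil(fraction * len(population))
    order = np.argsort(-np.asarray(phenotypic_fitnesses, dtype=float), kind="stable")
    return [population[i] for i in order[:n_sel]]


def _mutate_cells(cells: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    out = cells.ravel().copy()
    size = out.size
    for _ in range(k):
        a = int(rng.integers(size))
        b = int(rng.integers(size - 1))
        if b >= a:
            b += 1  # uniform pair with a != b
        out[a], out[b] = out[b], out[a]
    return out.reshape(cells.shape)


def mutate(genome: Genome, k: int, rng: np.random.Generator) -> Genome:
    """Swap ``k`` uniformly chosen cell pairs; counts and marker unchanged."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return Genome(Grid(_mutate_cells(genome.grid.cells, k, rng)), genome.mode_marker)


def _develop_one(
    cells: np.ndarray,
    target: TargetPattern,
    cfg: EvolutionConfig,
    dev_seed: int,
) -> tuple[np.ndarray, int, float]:
    """(phenotype cells, swaps used, distance moved) under the chosen engine."""
    if cfg.mode == "hardwired":
        return cells, 0, 0.0
    if cfg.engine == "fast":
        phen, swaps, dist, _, _ = develop_fast(
            cells, target.cells, cfg.mode, cfg.cap, dev_seed, cfg.max_stages
        )
        return phen, swaps, dist
    res = develop(
        Grid(cells),
        target,
        DevelopmentParams(
            mode=cfg.mode,
            competency_cap=cfg.cap,
            seed=dev_seed,
            max_stages=cfg.max_stages,
        ),
    )
    return res.phenotype.cells, res.swaps_total, res.distance_total


def _fitness_cols(mismatches: float, n: int) -> tuple[float, float]:
    d = math.sqrt(mismatches) / (n * n)
    return d, 9.0 ** (1.0 - d) / 9.0


def evolve(config: EvolutionConfig) -> EvolutionLog:
    """Run the full GA for ``config.runs`` seeded replicates."""
    target = config.target
    tcells = target.cells
    n = target.n
    m = config.population_size
    n_sel = math.ceil(config.selection_fraction * m)
    rows: list[dict] = []
    run_seeds: list[int] = []
    for run in range(config.runs):
        run_seed = int(
            np.random.SeedSequence([config.base_seed, run]).generate_state(1)[0]
            % (2**31 - 1)
        )
        run_seeds.append(run_seed)
        rng = np.random.default_rng(run_seed)
        init_seeds = rng.integers(0, 2**31 - 1, size=m)
        population = np.stack(
            [scramble(target, int(s)).cells for s in init_seeds]
        )  # (M, N, N)
        for gen in range(1, config.generations + 1):
            dev_seeds = rng.integers(0, 2**31 - 1, size=m)
            if config.mode == "hardwired":
                phenotypes = population
                swaps = np.zeros(m, dtype=np.int64)
                dists = np.zeros(m, dtype=float)
            else:
                phenotypes = np.empty_like(population)
                swaps = np.zeros(m, dtype=np.int64)
                dists = np.zeros(m, dtype=float)
                for i in range(m):
                    phenotypes[i], swaps[i], dists[i] = _develop_one(
                        population[i], target, config, int(dev_seeds[i])
                    )
            phen_mismatch = (phenotypes != tcells).sum(axis=(1, 2))
            best = int(np.argmin(phen_mismatch))  # ties -> lowest index
            gen_mismatch_best = int((population[best] != tcells).sum())
            pd_, pf = _fitness_cols(float(phen_mismatch[best]), n)
            gd_, gf = _fitness_cols(float(gen_mismatch_best), n)
            rows.append(
                {
                    "run": run,
                    "generation": gen,
                    "best_phen_fitness": pf,
                    "best_phen_d": pd_,
                    "best_gen_fitness": gf,
                    "best_gen_d": gd_,
                    "competency_used": int(swaps[best]),
                    "distance_moved": float(dists[best]),
                }
            )
            # selection (stable ties by index) + elitist repopulation
            order = np.argsort(phen_mismatch, kind="stable")
            parents = population[order[:n_sel]]
            children = np.empty((m - n_sel, n, n), dtype=population.dtype)
            parent_picks = rng.integers(0, n_sel, size=m - n_sel)
            for i, p in enumerate(parent_picks):
                children[i] = _mutate_cells(parents[p], config.mutation_swaps, rng)
            population = np.concatenate([parents, children], axis=0)
    frame = pd.DataFrame(rows)
    return EvolutionLog(frame=frame, config=config, run_seeds=run_seeds)
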