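"""The developmental engine: movement, blocking, tunneling, budgets."""

import math

import numpy as np
import pytest

from morphoglue import (
    Development,
    DevelopmentParams,
    Grid,
    Quiescence,
    TargetPattern,
    choose_destination,
    default_cap,
    develop,
    make_pattern,
    scramble,
    select_mover,
)
from morphoglue.signaling import DistressRecord


def _dev(embryo, target, **kw):
    e = np.asarray(embryo, dtype=np.uint8)
    t = TargetPattern("t", Grid(np.asarray(target, dtype=np.uint8)))
    return Development(Grid(e), t, DevelopmentParams(**kw))


def replay(genome_cells, trace):
    """Independent replay oracle: apply every recorded swap in order."""
    cells = genome_cells.copy()
    for ev in trace:
        for (a, b) in ev.swap_ops:
            cells[a], cells[b] = cells[b], cells[a]
    return cells


# ---------------------------------------------------------------------------
# mover selection and destination choice
# ---------------------------------------------------------------------------

def test_select_mover_single_and_empty(rng):
    assert select_mover([(3, 4)], rng) == (3, 4)
    with pytest.raises(Quiescence):
        select_mover([], rng)


def test_select_mover_uniform_frequencies(rng):
    cells = [(0, 0), (5, 5)]
    draws = [select_mover(cells, rng) for _ in range(10_000)]
    frac = sum(d == (0, 0) for d in draws) / 10_000
    assert abs(frac - 0.5) < 0.02


def test_choose_destination_argmax_ties_and_idle(rng):
    rec = DistressRecord(receiver=(0, 0), entries={(1, 1): 0.5, (2, 2): 0.2})
    assert choose_destination(rec, rng) == (1, 1)
    tie = DistressRecord(receiver=(0, 0), entries={(1, 1): 0.5, (2, 2): 0.5})
    draws = [choose_destination(tie, rng) for _ in range(10_000)]
    frac = sum(d == (1, 1) for d in draws) / 10_000
    assert abs(frac - 0.5) < 0.02
    assert choose_destination(DistressRecord(receiver=(0, 0)), rng) is None


# ---------------------------------------------------------------------------
# single moves
# ---------------------------------------------------------------------------

def _straight_line_setup(mode):
    """Mover at (2,0) must reach (2,4); the path cells are all stressed."""
    target = np.zeros((5, 5), int)
    target[2, 4] = 1  # destination wants a 1
    embryo = target.copy()
    embryo[2, 4] = 0
    embryo[2, 0] = 1  # the mover (stressed: target wants 0 here)
    for c in (1, 2, 3):
        embryo[2, c] = 1
        target[2, c] = 0  # stressed en-route cells
    # make en-route cells genuinely stressed: embryo 1 vs target 0
    return _dev(embryo, target, mode=mode, seed=0)


@pytest.mark.parametrize("mode", ["sharing", "no_sharing"])
def test_straight_path_through_stressed_cells(mode):
    dev = _straight_line_setup(mode)
    ev = dev.step_move((2, 0), (2, 4))
    assert ev.mover_final == (2, 4)
    assert ev.swaps_used == 4
    assert ev.tunneled == []
    assert not ev.blocked
    assert dev.embryo[2, 4] == 1  # mover's value delivered


def test_fixed_cell_blocks_without_sharing():
    target = np.zeros((5, 5), int)
    target[2, 4] = 1
    embryo = target.copy()
    embryo[2, 4] = 0
    embryo[2, 0] = 1  # mover
    embryo[2, 1] = 1
    target[2, 1] = 1  # en-route FIXED cell at (2,1)... adjacent to mover
    dev = _dev(embryo, target, mode="no_sharing", seed=0)
    ev = dev.step_move((2, 0), (2, 4))
    assert ev.blocked
    assert ev.mover_final == (2, 0)  # halts adjacent to the block
    assert ev.swaps_used == 0
    assert dev.stuck[2, 0]


def test_sharing_tunnels_through_fixed_cell_and_reverts_it():
    target = np.zeros((5, 5), int)
    target[2, 4] = 1
    embryo = target.copy()
    embryo[2, 4] = 0
    embryo[2, 0] = 1  # mover
    embryo[2, 2] = 1
    target[2, 2] = 1  # fixed cell in the way
    before = embryo[2, 2]
    dev = _dev(embryo, target, mode="sharing", seed=0)
    ev = dev.step_move((2, 0), (2, 4))
    assert ev.mover_final == (2, 4)
    assert (2, 2) in ev.tunneled
    assert dev.embryo[2, 2] == before  # reverted to its blocking state
    assert dev.embryo[2, 2] == target[2, 2]
    # tunnel passage still costs swaps along the whole path
    assert ev.swaps_used == 4
    # the mover shared stress around its position when it hit the block
    assert len(ev.shared) > 0


def test_move_truncated_by_budget():
    dev = _straight_line_setup("sharing")
    dev.cap = 2
    ev = dev.step_move((2, 0), (2, 4))
    assert ev.truncated
    assert ev.swaps_used == 2
    assert ev.mover_final == (2, 2)


# ---------------------------------------------------------------------------
# whole developments
# ---------------------------------------------------------------------------

def test_hardwired_development_is_identity(face30):
    genome = scramble(face30, 3)
    res = develop(genome, face30, DevelopmentParams(mode="hardwired"))
    assert res.phenotype == genome
    assert res.swaps_total == 0
    assert res.distance_total == 0.0
    assert res.stages == 0
    assert res.trace == []


def test_perfect_genome_develops_in_zero_stages(face30):
    res = develop(face30.grid, face30, DevelopmentParams(mode="sharing"))
    assert res.stages == 0
    assert res.status == "completed"


def test_sharing_development_completes_and_replays(face30):
    completed = 0
    for seed in range(20):
        genome = scramble(face30, seed)
        res = develop(genome, face30, DevelopmentParams(mode="sharing", seed=seed))
        # replay oracle: the trace fully determines the phenotype
        assert np.array_equal(replay(genome.cells, res.trace), res.phenotype.cells)
        mismatch = int((res.phenotype.cells != face30.cells).sum())
        assert mismatch == sum(
            int(res.phenotype.cells[r, c] != face30.cells[r, c])
            for r in range(30)
            for c in range(30)
        )
        if mismatch == 0:
            completed += 1
    assert completed > 10  # majority of seeds reach the target


def test_distance_total_matches_path_replay(face30):
    res = develop(scramble(face30, 4), face30, DevelopmentParams(mode="sharing", seed=4))
    total = sum(
        math.hypot(b[0] - a[0], b[1] - a[1])
        for ev in res.trace
        for a, b in zip(ev.path, ev.path[1:])
    )
    assert res.distance_total == pytest.approx(total)


@pytest.mark.parametrize("mode", ["sharing", "no_sharing", "hardwired"])
def test_cell_type_counts_conserved(mode, face30):
    for seed in range(5):
        genome = scramble(face30, seed)
        res = develop(genome, face30, DevelopmentParams(mode=mode, seed=seed))
        assert res.phenotype.type_counts() == genome.type_counts()


@pytest.mark.parametrize("mode", ["sharing", "no_sharing"])
def test_budget_bound_always_holds(mode, face30):
    for seed in range(5):
        cap = 50
        res = develop(
            scramble(face30, seed),
            face30,
            DevelopmentParams(mode=mode, seed=seed, competency_cap=cap),
        )
        assert res.swaps_total <= cap


def test_fixed_cells_never_change_in_sharing_mode(face30):
    """Tunneled fixed cells hold their value across every move event."""
    for seed in range(5):
        genome = scramble(face30, seed)
        res = develop(genome, face30, DevelopmentParams(mode="sharing", seed=seed))
        cells = genome.cells.copy()
        for ev in res.trace:
            before = {pos: cells[pos] for pos in ev.tunneled}
            for (a, b) in ev.swap_ops:
                cells[a], cells[b] = cells[b], cells[a]
            for pos, val in before.items():
                assert cells[pos] == val, f"tunneled cell {pos} changed value"


def test_blocked_cell_theorem_no_sharing():
    """A stressed cell walled in by fixed cells can never move without sharing."""
    target = np.zeros((7, 7), int)
    embryo = target.copy()
    embryo[3, 3] = 1  # walled-in misplaced cell (neighbors all fixed 0s)
    # a second stressed pair far away generates vacancies and movement
    embryo[0, 6] = 1
    target[0, 6] = 0
    target[0, 0] = 1
    embryo[0, 0] = 0
    dev = _dev(embryo, target, mode="no_sharing", seed=1)
    res = dev.run()
    # the walled-in cell is exactly where it started
    assert res.phenotype.cells[3, 3] == 1


def test_sharing_frees_walled_in_cell():
    target = np.zeros((7, 7), int)
    embryo = target.copy()
    embryo[3, 3] = 1
    target[0, 0] = 1
    embryo[0, 0] = 0
    dev = _dev(embryo, target, mode="sharing", seed=1)
    res = dev.run()
    assert res.status == "completed"
    assert res.phenotype.cells[3, 3] == 0
    assert res.phenotype.cells[0, 0] == 1


def test_no_sharing_development_is_short_and_quiescent(face30):
    res = develop(scramble(face30, 8), face30, DevelopmentParams(mode="no_sharing", seed=8))
    assert res.status == "quiescent"
    assert res.stages < 100
    assert int((res.phenotype.cells != face30.cells).sum()) > 0


def test_development_is_seed_deterministic(face30):
    a = develop(scramble(face30, 2), face30, DevelopmentParams(mode="sharing", seed=9))
    b = develop(scramble(face30, 2), face30, DevelopmentParams(mode="sharing", seed=9))
    assert a.phenotype == b.phenotype
    assert a.swaps_total == b.swaps_total
    assert [ev.path for ev in a.trace] == [ev.path for ev in b.trace]


def test_zero_cap_collapses_phenotype_to_genotype(face30):
    for mode in ("sharing", "no_sharing", "hardwired"):
        genome = scramble(face30, 6)
        res = develop(
            genome, face30, DevelopmentParams(mode=mode, seed=6, competency_cap=0)
        )
        assert res.phenotype == genome
        assert res.swaps_total == 0


def test_default_cap_values():
    assert default_cap(30) == 4725
    assert default_cap(20) == 2100


def test_size_mismatch_rejected(face30, face12):
    with pytest.raises(ValueError):
        develop(face12.grid, face30)
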