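"""Radius of influence, stress-map observables, sequential runs, statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from morphoglue import (
    DevelopmentParams,
    Grid,
    TargetPattern,
    aggregate_runs,
    compare_populations,
    compute_stress_map,
    develop,
    make_pattern,
    radius_of_influence,
    run_sequential,
    scramble,
    similarity,
    stress_gradient,
)
from morphoglue.patterns import SUBTARGET_SEQUENCE


# ---------------------------------------------------------------------------
# radius of influence
# ---------------------------------------------------------------------------

def test_hardwired_trace_gives_empty_series(face30):
    res = develop(scramble(face30, 0), face30, DevelopmentParams(mode="hardwired"))
    assert len(radius_of_influence(res)) == 0


def test_diagonal_dislodgement_has_radius_sqrt2():
    # mover at (1,1), destination the diagonal neighbor (2,2)
    target = np.zeros((5, 5), int)
    target[2, 2] = 1
    embryo = target.copy()
    embryo[2, 2] = 0
    embryo[1, 1] = 1
    from morphoglue.development import Development

    dev = Development(
        Grid(embryo.astype(np.uint8)),
        TargetPattern("t", Grid(target.astype(np.uint8))),
        DevelopmentParams(mode="sharing", seed=0),
    )
    ev = dev.step_move((1, 1), (2, 2))
    assert ev.max_dislodge_radius == pytest.approx(math.sqrt(2))


def test_influence_bounded_by_grid_diameter(face30):
    res = develop(scramble(face30, 5), face30, DevelopmentParams(mode="sharing", seed=5))
    series = radius_of_influence(res)
    assert len(series) == res.stages
    assert series.max() <= math.sqrt(2) * 29


def test_sharing_influence_dominates_no_sharing(face30):
    """Stress sharing widens and prolongs the radius of influence."""
    share_first, share_len, block_first, block_len = [], [], [], []
    for seed in range(10):
        genome = scramble(face30, seed)
        rs = radius_of_influence(
            develop(genome, face30, DevelopmentParams(mode="sharing", seed=seed))
        )
        rb = radius_of_influence(
            develop(genome, face30, DevelopmentParams(mode="no_sharing", seed=seed))
        )
        share_first.append(rs[0])
        share_len.append(len(rs))
        block_first.append(rb[0])
        block_len.append(len(rb))
    assert np.median(share_first) > np.median(block_first)
    assert np.median(share_len) > np.median(block_len)


# ---------------------------------------------------------------------------
# gradients and similarity
# ---------------------------------------------------------------------------

def test_zero_stress_gives_zero_gradient(face30):
    grad = stress_gradient(compute_stress_map(face30.grid, face30))
    assert np.all(grad.d_row == 0) and np.all(grad.d_col == 0)


def test_single_stressed_cell_gradient_is_antisymmetric():
    target = np.zeros((7, 7), int)
    embryo = target.copy()
    embryo[3, 3] = 1
    grad = stress_gradient(
        compute_stress_map(Grid(embryo.astype(np.uint8)), Grid(target.astype(np.uint8)))
    )
    # central differences around the spike: +1/2 before, -1/2 after
    assert grad.d_row[2, 3] == pytest.approx(0.5)
    assert grad.d_row[4, 3] == pytest.approx(-0.5)
    assert grad.d_col[3, 2] == pytest.approx(0.5)
    assert grad.d_col[3, 4] == pytest.approx(-0.5)
    assert grad.d_row[3, 3] == 0.0


def test_similarity_endpoints(face30):
    assert similarity(face30.cells, face30) == 1.0
    assert similarity(1 - face30.cells, face30) == 0.0


def test_similarity_complement_identity(face30, rng):
    s = rng.integers(0, 2, (30, 30))
    assert similarity(s, face30) + similarity(1 - s, face30) == pytest.approx(1.0)


def test_random_balanced_similarity_near_half(face30):
    vals = [
        similarity(np.random.default_rng(seed).integers(0, 2, (30, 30)), face30)
        for seed in range(300)
    ]
    assert abs(np.mean(vals) - 0.5) < 0.02


def test_rms_similarity_variant(face30):
    vals = [
        similarity(
            np.random.default_rng(seed).integers(0, 2, (30, 30)), face30, method="rms"
        )
        for seed in range(100)
    ]
    assert 0.25 < np.mean(vals) < 0.33  # ~1 - 1/sqrt(2)


# ---------------------------------------------------------------------------
# sequential morphogenesis
# ---------------------------------------------------------------------------

def test_single_element_sequence_reduces_to_plain_develop(face30):
    params = DevelopmentParams(mode="sharing", seed=3)
    series = run_sequential([face30], "sharing", params)
    plain = develop(scramble(face30, 3), face30, params)
    assert np.allclose(series.values, plain.stress_series)
    assert series.switch_stages == []
    assert series.swaps_total == plain.swaps_total


def test_sharing_sequential_reaches_zero_stress(face30):
    sequence = [make_pattern(k, 30) for k in SUBTARGET_SEQUENCE]
    series = run_sequential(sequence, "sharing", DevelopmentParams(mode="sharing", seed=1))
    assert series.zero_step is not None
    assert series.values[-1] == 0.0
    assert len(series.switch_stages) == len(sequence) - 1


def test_no_sharing_sequential_stalls_above_zero(face30):
    sequence = [make_pattern(k, 30) for k in SUBTARGET_SEQUENCE]
    series = run_sequential(
        sequence, "no_sharing", DevelopmentParams(mode="no_sharing", seed=1)
    )
    assert series.zero_step is None
    assert series.terminal_stress > 0.0


def test_sequential_stress_decreases_between_switches(face30):
    sequence = [make_pattern(k, 30) for k in SUBTARGET_SEQUENCE]
    series = run_sequential(sequence, "sharing", DevelopmentParams(mode="sharing", seed=2))
    switch_set = set(series.switch_stages)
    grace = set()
    for s in series.switch_stages:
        grace.add(s + 1)
    for i in range(1, len(series.values)):
        stage = i + 1
        if stage in switch_set or stage in grace or (stage - 1) in switch_set:
            continue
        # strictly decreasing away from switches (non-strict only at the end)
        assert series.values[i] <= series.values[i - 1]


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        run_sequential([], "sharing")


# ---------------------------------------------------------------------------
# run statistics
# ---------------------------------------------------------------------------

def test_aggregate_identical_runs_zero_width():
    mean, half = aggregate_runs(np.tile(np.arange(5.0), (4, 1)))
    assert np.allclose(mean, np.arange(5.0))
    assert np.allclose(half, 0.0)


def test_aggregate_two_runs_mean():
    mean, _ = aggregate_runs(np.array([[0.0], [1.0]]))
    assert mean[0] == pytest.approx(0.5)


def test_aggregate_matches_closed_form(rng):
    values = rng.normal(size=(10, 3))
    mean, half = aggregate_runs(values)
    s = values.std(axis=0, ddof=1)
    expected = sps.t.ppf(0.975, 9) * s / math.sqrt(10)
    assert np.allclose(half, expected)
    with pytest.raises(ValueError):
        aggregate_runs(values[:1])


def test_compare_identical_samples_degenerate():
    res = compare_populations([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert res.statistic == 0.0 and res.pvalue == 1.0 and res.degenerate


def test_compare_separated_samples():
    res = compare_populations([0.0, 0.01, 0.02], [10.0, 10.01, 10.02])
    assert res.pvalue < 1e-6


def test_compare_matches_hand_computed_welch():
    # a = [1,2,3,4]: mean 2.5, var 5/3; b = [6,7,8,10]: mean 7.75, var 35/12
    # t = (2.5 - 7.75) / sqrt(5/12 + 35/48) = -5.25 / sqrt(55/48)
    a = [1.0, 2.0, 3.0, 4.0]
    b = [6.0, 7.0, 8.0, 10.0]
    expected_t = -5.25 / math.sqrt(5 / 12 + 35 / 48)
    res = compare_populations(a, b)
    assert res.statistic == pytest.approx(expected_t)
    with pytest.raises(ValueError):
        compare_populations([1.0], [1.0, 2.0])
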