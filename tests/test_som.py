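"""SOM core: winner search, neighborhood, update rule, training dynamics.

The distance, winner and update operations are checked against
independently coded scalar-loop oracles; training is checked for its
fixed-point and quantization-error behavior.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somhebb import (
    TrainingSchedule,
    WeightMap,
    distance,
    find_winner,
    init_map,
    neighborhood,
    quantization_error,
    train_som,
    update_weights,
)
from somhebb.som import grid_coordinates


# --- independent oracles (plain Python loops, no numpy vectorization) -------


def oracle_distance(x, m):
    s = 0.0
    for xi, mi in zip(x, m):
        s += (xi - mi) ** 2
    return math.sqrt(s)


def oracle_winner(x, weights, enabled):
    best, best_d = None, float("inf")
    for k in range(len(weights)):
        if not enabled[k]:
            continue
        d = oracle_distance(x, weights[k])
        if d < best_d:  # strict: keeps the lowest index on ties
            best, best_d = k, d
    if best is None:
        raise ValueError("no enabled neurons")
    return best

def oracle_update(weights, x, C, alpha_t, sigma_t, coords):
    out = [row[:] for row in weights.tolist()]
    for k in range(len(out)):
        dr = coords[C][0] - coords[k][0]
        dc = coords[C][1] - coords[k][1]
        h = alpha_t * math.exp(-(dr * dr + dc * dc) / sigma_t**2)
        for j in range(len(out[k])):
            out[k][j] = out[k][j] + h * (x[j] - out[k][j])
    return np.asarray(out)


# --- distance ---------------------------------------------------------------


def test_distance_examples():
    assert distance([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert distance([3.0, 4.0], [0.0, 0.0]) == 5.0
    with pytest.raises(ValueError, match="dimension mismatch"):
        distance([1.0], [1.0, 2.0])


def test_distance_against_oracle(rng):
    for _ in range(100):
        x = rng.normal(size=48)
        m = rng.normal(size=48)
        assert distance(x, m) == pytest.approx(oracle_distance(x, m), abs=1e-12)


# --- winner search ----------------------------------------------------------


def test_winner_exact_match(rng):
    wm = init_map(5, 6, rng.normal(size=(20, 6)), seed=0)
    x = wm.weights[17].copy()
    wm.weights[np.arange(25) != 17] += 10.0
    assert find_winner(x, wm) == 17


def test_winner_tie_breaks_to_lowest_index():
    weights = np.ones((16, 2)) * 5.0
    weights[3] = [1.0, 0.0]
    weights[9] = [-1.0, 0.0]  # same distance from origin as neuron 3
    wm = WeightMap(weights, 4)
    assert find_winner(np.zeros(2), wm) == 3


def test_winner_respects_enabled_mask():
    wm = WeightMap(np.array([[0.0], [1.0], [2.0], [9.0]]), 2)
    enabled = np.array([False, True, True, True])
    assert find_winner(np.array([0.0]), wm, enabled) == 1
    with pytest.raises(ValueError, match="no enabled neurons"):
        find_winner(np.array([0.0]), wm, np.zeros(4, dtype=bool))


def test_winner_against_oracle(rng):
    for _ in range(50):
        M = int(rng.integers(2, 6))
        D = int(rng.integers(1, 10))
        wm = WeightMap(rng.normal(size=(M * M, D)), M)
        enabled = rng.random(M * M) > 0.3
        if not enabled.any():
            enabled[0] = True
        x = rng.normal(size=D)
        assert find_winner(x, wm, enabled) == oracle_winner(x, wm.weights, enabled)


# --- neighborhood -----------------------------------------------------------


def test_neighborhood_values():
    coords = grid_coordinates(8)
    assert neighborhood(10, 10, 0.4, 2.0, coords) == pytest.approx(0.4)
    # grid distance^2 = 2 between (0,0) and (1,1): h = 0.5 * e^-2
    assert neighborhood(0, 9, 0.5, 1.0, coords) == pytest.approx(
        0.5 * math.exp(-2.0), abs=1e-6
    )
    with pytest.raises(ValueError, match="invalid radius"):
        neighborhood(0, 1, 0.5, 0.0, coords)


def test_neighborhood_decreases_with_grid_distance():
    coords = grid_coordinates(8)
    # along the first row: squared distance grows strictly
    values = [neighborhood(0, k, 0.5, 2.0, coords) for k in range(8)]
    assert all(a > b for a, b in zip(values, values[1:]))


# --- weight update ----------------------------------------------------------


def test_update_winner_snaps_with_unit_rate(rng):
    wm = WeightMap(rng.normal(size=(9, 4)), 3)
    x = rng.normal(size=4)
    out = update_weights(wm, x, C=4, alpha_t=1.0, sigma_t=1.0)
    np.testing.assert_allclose(out.weights[4], x, atol=1e-12)


def test_update_vanishes_at_zero_rate(rng):
    wm = WeightMap(rng.normal(size=(9, 4)), 3)
    x = rng.normal(size=4)
    out = update_weights(wm, x, C=0, alpha_t=1e-15, sigma_t=1.0)
    np.testing.assert_allclose(out.weights, wm.weights, atol=1e-12)


def test_update_against_oracle(rng):
    for _ in range(100):
        M = int(rng.integers(2, 5))
        D = int(rng.integers(1, 8))
        wm = WeightMap(rng.normal(size=(M * M, D)), M)
        x = rng.normal(size=D)
        C = int(rng.integers(M * M))
        alpha_t = float(rng.uniform(0.01, 1.0))
        sigma_t = float(rng.uniform(0.3, 3.0))
        out = update_weights(wm, x, C, alpha_t, sigma_t)
        expected = oracle_update(
            wm.weights, x, C, alpha_t, sigma_t, wm.grid_coords.tolist()
        )
        np.testing.assert_allclose(out.weights, expected, atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), alpha=st.floats(0.01, 1.0), sigma=st.floats(0.1, 4.0))
def test_update_is_convex_combination(seed, alpha, sigma):
    """Every updated component lies between its old value and the input's."""
    rng = np.random.default_rng(seed)
    wm = WeightMap(rng.normal(size=(16, 5)), 4)
    x = rng.normal(size=5)
    out = update_weights(wm, x, C=int(rng.integers(16)), alpha_t=alpha, sigma_t=sigma)
    lo = np.minimum(wm.weights, x)
    hi = np.maximum(wm.weights, x)
    assert np.all(out.weights >= lo - 1e-12)
    assert np.all(out.weights <= hi + 1e-12)


# --- initialisation and training -------------------------------------------


def test_init_map_range_and_determinism(rng):
    X = rng.normal(size=(30, 5))
    X[:, 2] = 7.0  # degenerate dimension
    a = init_map(8, 5, X, seed=3)
    b = init_map(8, 5, X, seed=3)
    np.testing.assert_array_equal(a.weights, b.weights)
    assert a.weights.shape == (64, 5)
    assert np.all(a.weights[:, 2] == 7.0)
    assert np.all(a.weights >= X.min(axis=0)) and np.all(a.weights <= X.max(axis=0))
    with pytest.raises(ValueError, match="cannot initialize"):
        init_map(4, 5, np.empty((0, 5)), seed=0)


def test_single_vector_training_converges():
    x = np.array([1.0, -2.0, 0.5])
    wm = train_som(x[None, :], M=4, schedule=TrainingSchedule(epochs=100, seed=0))
    winner = find_winner(x, wm)
    assert distance(x, wm.weights[winner]) < 1e-6


def test_quantization_error_decreases_on_two_clusters():
    """Training must tighten the map around well-separated clusters."""
    improved = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [
                rng.normal(0.0, 0.3, size=(20, 8)),
                rng.normal(5.0, 0.3, size=(20, 8)),
            ]
        )
        schedule = TrainingSchedule(epochs=30, seed=seed)
        before = quantization_error(X, init_map(4, 8, X, seed=seed))
        after = quantization_error(X, train_som(X, M=4, schedule=schedule))
        if after < before:
            improved += 1
    assert improved == 10


def test_training_determinism(rng):
    X = rng.normal(size=(40, 6))
    schedule = TrainingSchedule(epochs=20, seed=5)
    a = train_som(X, M=5, schedule=schedule)
    b = train_som(X, M=5, schedule=schedule)
    np.testing.assert_array_equal(a.weights, b.weights)


def test_trained_weights_stay_in_data_range(rng):
    X = rng.uniform(-3, 9, size=(50, 4))
    wm = train_som(X, M=6, schedule=TrainingSchedule(epochs=25, seed=2))
    eps = 1e-9
    assert np.all(wm.weights >= X.min(axis=0) - eps)
    assert np.all(wm.weights <= X.max(axis=0) + eps)


def test_schedule_validation():
    with pytest.raises(ValueError):
        TrainingSchedule(alpha0=1.5)
    with pytest.raises(ValueError):
        TrainingSchedule(epochs=0)
    with pytest.raises(ValueError):
        TrainingSchedule(sigma0=0.1, sigma_final=0.5)
    s = TrainingSchedule(epochs=10, decay="exponential")
    a0, s0 = s.at(0, 100, 8)
    aT, sT = s.at(99, 100, 8)
    assert a0 == pytest.approx(0.5) and s0 == pytest.approx(4.0)
    assert aT == pytest.approx(0.01) and sT == pytest.approx(0.5)
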