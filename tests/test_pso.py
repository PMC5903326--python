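"""Swarm feature selection: mask decoding and pairing, the multi-objective
fitness, the velocity update (hand-evaluated), monotone best-keeping, early
stopping, and agreement with exhaustive enumeration on a small search space."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibci.csp import FeatureTable
from mibci.pso import (FeatureLayout, FitnessEvaluator, PsoConfig, SwarmState,
                       decode_mask, fitness, pair_closure, select_features,
                       step_swarm)

LAYOUT = FeatureLayout(6, 11)


def _table(rng, n=60, d=66, n_bands=6, n_filters=11, signal_cols=(), shift=1.5):
    y = np.array(["MI", "REST"] * (n // 2), dtype="U4")
    X = rng.standard_normal((n, d))
    for col in signal_cols:
        X[y == "MI", col] += shift
    return FeatureTable(X, y, n_bands=n_bands, n_filters=n_filters)


class TestMaskDecoding:
    def test_all_below_threshold_forces_one_pair(self):
        mask = decode_mask(np.full(66, 0.49), 0.5, LAYOUT)
        assert mask.sum() in (1, 2)  # forced dimension plus its complement
        assert mask.any()

    def test_all_ones_selects_everything(self):
        assert decode_mask(np.ones(66), 0.5, LAYOUT).sum() == 66

    def test_single_selection_adds_band_complement(self):
        position = np.zeros(66)
        position[0] = 0.9        # band 1, filter 1
        mask = decode_mask(position, 0.5, LAYOUT)
        assert mask[0] and mask[10]   # filter 11 of band 1 added
        assert mask.sum() == 2

    def test_pairing_examples(self):
        mask = np.zeros(66, dtype=bool)
        mask[11 + 2] = True      # band 2, filter 3
        closed = pair_closure(mask, LAYOUT)
        assert closed[11 + 8]    # band 2, filter 9 (= 12 - 3)
        assert closed.sum() == 2

        mask = np.zeros(66, dtype=bool)
        mask[33 + 5] = True      # band 4, filter 6: self-complementary
        assert pair_closure(mask, LAYOUT).sum() == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=66, max_size=66))
    def test_pair_closure_idempotent_and_monotone(self, bits):
        mask = np.array(bits, dtype=bool)
        closed = pair_closure(mask, LAYOUT)
        assert np.array_equal(pair_closure(closed, LAYOUT), closed)
        assert np.all(closed[mask])  # never drops a selection


class TestFitness:
    def test_zero_error_full_mask_scores_one(self, rng):
        table = _table(rng, signal_cols=range(66), shift=8.0)
        value = fitness(np.ones(66, dtype=bool), table)
        assert value == pytest.approx(1.0)

    def test_total_error_full_mask_scores_three(self, rng):
        table = _table(rng, signal_cols=range(66), shift=8.0)
        flipped = FeatureTable(table.X,
                               np.where(table.labels == "MI", "REST", "MI"),
                               6, 11)
        value = fitness(np.ones(66, dtype=bool), table, eval_features=flipped)
        assert value == pytest.approx(3.0)

    def test_half_error_half_mask_scores_one_point_five(self, rng):
        # identical class distributions -> zero weights -> all-REST
        # prediction -> err = 0.5 on balanced data; 33 = 3 full bands
        table = _table(rng)
        table.X[:, :33] = 1.0
        mask = np.zeros(66, dtype=bool)
        mask[:33] = True
        assert fitness(mask, table) == pytest.approx(2 * 0.5 + 33 / 66)

    def test_evaluator_matches_lda_route(self, rng):
        table = _table(rng, signal_cols=(3, 17))
        evaluator = FitnessEvaluator(table)
        for _ in range(20):
            mask = pair_closure(rng.random(66) > 0.6, LAYOUT)
            if not mask.any():
                continue
            value, err, nselec = evaluator(mask)
            assert value == pytest.approx(fitness(mask, table), abs=1e-9)
            assert nselec == mask.sum()

    def test_bounds_on_random_masks(self, rng):
        table = _table(rng, signal_cols=(5,))
        evaluator = FitnessEvaluator(table)
        for _ in range(200):
            mask = decode_mask(rng.random(66), 0.5, LAYOUT)
            value, err, _ = evaluator(mask)
            assert 0.0 < value <= 3.0
            assert 0.0 <= err <= 1.0


class _OnesRng:
    """Stub RNG: uniform() returns the upper bound everywhere (r1 = r2 = 1)."""

    def uniform(self, low, high, size):
        return np.full(size, high)


def test_velocity_update_hand_example():
    # v' = 0.5*0.1 + 1*(0.7-0.5) + 1*(0.9-0.5) = 0.65; x' = 1.15 -> clamp 1.0
    config = PsoConfig(n_particles=1, inertia_start=0.5, inertia_end=0.5)
    layout = FeatureLayout(1, 1)
    state = SwarmState(
        positions=np.array([[0.5]]), velocities=np.array([[0.1]]),
        pbest_positions=np.array([[0.7]]), pbest_values=np.array([0.0]),
        gbest_position=np.array([0.9]), gbest_value=0.0, gbest_err=0.0,
        gbest_nselec=1, generation=0, rng=_OnesRng())
    step_swarm(state, config, lambda mask: (1.0, 0.5, 1), layout)
    assert state.velocities[0, 0] == pytest.approx(0.65)
    assert state.positions[0, 0] == pytest.approx(1.0)


def test_stationary_fixed_point():
    config = PsoConfig(n_particles=3, inertia_start=0.5, inertia_end=0.5)
    layout = FeatureLayout(2, 1)
    x = np.full((3, 2), 0.6)
    state = SwarmState(
        positions=x.copy(), velocities=np.zeros((3, 2)),
        pbest_positions=x.copy(), pbest_values=np.zeros(3),
        gbest_position=x[0].copy(), gbest_value=0.0, gbest_err=0.0,
        gbest_nselec=1, generation=0, rng=np.random.default_rng(0))
    step_swarm(state, config, lambda mask: (1.0, 0.5, 1), layout)
    assert np.array_equal(state.positions, x)


class TestSelectFeatures:
    def test_separable_column_early_stop(self, rng):
        """Zero training error halts the search before the generation budget;
        the returned mask reproduces that zero error.  The error-based stop
        fires at the first zero-error mask, so the feature count is not
        minimised further on separable data."""
        table = _table(rng, signal_cols=(7,), shift=10.0)
        mask, trace = select_features(table, PsoConfig(seed=3))
        assert trace["best_err"].iloc[-1] == 0.0
        assert len(trace) - 1 < 50          # stopped before the budget
        assert fitness(mask, table) == pytest.approx(mask.sum() / 66)

    def test_global_best_monotone(self, rng):
        table = _table(rng, signal_cols=(2,), shift=0.5)
        _, trace = select_features(table, PsoConfig(seed=4, n_generations=15))
        assert np.all(np.diff(trace["best_fitness"]) <= 0)

    def test_same_seed_reproducible(self, rng):
        table = _table(rng, signal_cols=(9,))
        m1, t1 = select_features(table, PsoConfig(seed=5, n_generations=10))
        m2, t2 = select_features(table, PsoConfig(seed=5, n_generations=10))
        assert np.array_equal(m1, m2)
        assert t1.equals(t2)

    def test_noise_features_drive_selection_count_down(self, rng):
        nselecs = []
        for seed in range(5):
            table = _table(np.random.default_rng(100 + seed), n=200)
            mask, _ = select_features(table, PsoConfig(seed=seed))
            nselecs.append(mask.sum())
        assert np.median(nselecs) < 33

    def test_matches_exhaustive_optimum_on_small_space(self, rng):
        layout = FeatureLayout(6, 1)
        table = _table(rng, n=60, d=6, n_bands=6, n_filters=1,
                       signal_cols=(2,), shift=0.9)
        table.X[table.labels == "MI", 4] += 0.6
        best = min(
            fitness(pair_closure(
                np.array([(bits >> i) & 1 for i in range(6)], dtype=bool),
                layout), table)
            for bits in range(1, 64))
        hits = sum(
            abs(fitness(select_features(table, PsoConfig(seed=s), layout)[0],
                        table) - best) < 1e-12
            for s in range(10))
        assert hits >= 9

    def test_holdout_mode_runs(self, rng):
        table = _table(rng, signal_cols=(1,))
        mask, trace = select_features(
            table, PsoConfig(seed=6, n_generations=5, eval_mode="holdout"))
        assert mask.any()
        assert len(trace) >= 1
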