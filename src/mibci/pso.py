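"""Particle-swarm feature selection with a multi-objective fitness.

Each particle is a continuous vector in [0, 1]^D over the D extracted
features (D = 66 for 6 bands x 11 spatial filters).  Thresholding a position
at 0.5 yields a candidate feature subset, which is closed under the CSP
pairing rule: within each band, spatial filters come in (first, last)
eigenvalue pairs, so selecting filter j also selects filter n_filters+1-j
(the middle filter of an odd bank is its own complement).

The fitness to MINIMISE is

    value = 2 * err + nselec / D

where err is the LDA classification error measured, by default, on the
training set itself (resubstitution) and nselec the number of selected
features.  Doubling err prioritises error reduction over parsimony.  The
swarm uses the canonical velocity update with inertia decaying linearly from
1 to 0 over the generations, cognitive/social constants c1 = c2 = 1, velocity
magnitude clamped to 1 and positions clamped to [0, 1].  The search stops at
zero training error or after the generation budget (50 x 50 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import lda
from .csp import FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureLayout:
    """Band-major layout of the feature vector: n_bands blocks of n_filters."""

    n_bands: int = 6
    n_filters: int = 11

    @property
    def dimension(self) -> int:
        return self.n_bands * self.n_filters

    def complement_indices(self) -> np.ndarray:
        """complement[i] = index of the paired feature of feature i."""
        within = np.arange(self.n_filters)[::-1]
        return np.concatenate(
            [b * self.n_filters + within for b in range(self.n_bands)])


@dataclass(frozen=True)
class PsoConfig:
    n_particles: int = 50
    n_generations: int = 50
    c1: float = 1.0
    c2: float = 1.0
    inertia_start: float = 1.0
    inertia_end: float = 0.0
    position_bounds: tuple[float, float] = (0.0, 1.0)
    max_speed: float = 1.0
    selection_threshold: float = 0.5
    err_weight: float = 2.0
    seed: int = 0
    eval_mode: str = "resubstitution"   # or "holdout"
    holdout_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.selection_threshold < 1.0:
            raise ValueError("selection_threshold must lie in (0, 1)")
        if self.max_speed <= 0 or self.position_bounds[1] <= self.position_bounds[0]:
            raise ValueError("bounds must be positive/ordered")
        if self.eval_mode not in ("resubstitution", "holdout"):
            raise ValueError(f"unknown eval_mode {self.eval_mode!r}")

    def inertia(self, generation: int) -> float:
        """Linear inertia schedule over generations 1..n_generations."""
        if self.n_generations <= 1:
            return self.inertia_end
        frac = (generation - 1) / (self.n_generations - 1)
        frac = min(max(frac, 0.0), 1.0)
        return self.inertia_start + frac * (self.inertia_end - self.inertia_start)


@dataclass
class SwarmState:
    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_values: np.ndarray
    gbest_position: np.ndarray
    gbest_value: float
    gbest_err: float
    gbest_nselec: int
    generation: int
    rng: np.random.Generator
    history: list = field(default_factory=list)


def pair_closure(mask: np.ndarray, layout: FeatureLayout) -> np.ndarray:
    """Add the complement of every selected feature (idempotent)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != layout.dimension:
        raise ValueError("mask length does not match layout dimension")
    return mask | mask[layout.complement_indices()]


def decode_mask(position: np.ndarray, threshold: float = 0.5,
                layout: FeatureLayout = FeatureLayout()) -> np.ndarray:
    """Threshold a particle position into a pair-closed feature mask.

    A position selecting nothing is repaired by forcing on the dimension with
    the highest position value before pair closure, so masks are never empty.
    """
    position = np.asarray(position, dtype=np.float64)
    mask = position >= threshold
    if not mask.any():
        mask = mask.copy()
        mask[int(np.argmax(position))] = True
    return pair_closure(mask, layout)


class FitnessEvaluator:
    """Cached fitness of pair-closed masks against a fixed training table.

    Precomputes per-class feature sums and scatter matrices once, so each
    masked LDA subproblem reduces to slicing and a small linear solve; results
    are memoised by mask.  Numerically equivalent to calling
    :func:`fitness` (which goes through :mod:`mibci.lda`) — a unit test
    enforces the agreement.
    """

    def __init__(self, train: FeatureTable, eval_table: FeatureTable | None = None,
                 err_weight: float = 2.0):
        self.err_weight = err_weight
        self.dimension = train.n_features
        X, y = train.X, train.labels
        self._stats = {}
        for cls in (lda.MI, lda.REST):
            Xc = X[y == cls]
            if Xc.shape[0] < 2:
                raise ValueError(f"training table lacks class {cls}")
            self._stats[cls] = (Xc.shape[0], Xc.sum(axis=0), Xc.T @ Xc)
        ev = eval_table if eval_table is not None else train
        self._eval_X = ev.X
        self._eval_is_mi = ev.labels == lda.MI
        self._cache: dict[bytes, tuple[float, float, int]] = {}

    def __call__(self, mask: np.ndarray) -> tuple[float, float, int]:
        """Return (value, err, nselec) for a boolean mask."""
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        idx = np.flatnonzero(mask)
        nselec = idx.size
        n1, sum1, scat1 = self._stats[lda.MI]
        n2, sum2, scat2 = self._stats[lda.REST]
        mu1 = sum1[idx] / n1
        mu2 = sum2[idx] / n2
        pooled = (scat1[np.ix_(idx, idx)] - n1 * np.outer(mu1, mu1)
                  + scat2[np.ix_(idx, idx)] - n2 * np.outer(mu2, mu2)) \
            / (n1 + n2 - 2)
        delta = mu1 - mu2
        try:
            w = np.linalg.solve(pooled, delta)
        except np.linalg.LinAlgError:
            ridge = lda.SHRINKAGE * max(np.mean(np.diag(pooled)),
                                        np.finfo(float).tiny)
            w = np.linalg.solve(pooled + ridge * np.eye(nselec), delta)
        bias = -float(w @ (mu1 + mu2) / 2.0)
        scores = self._eval_X[:, idx] @ w + bias
        predicted_mi = scores > 0
        err = float(np.mean(predicted_mi != self._eval_is_mi))
        value = self.err_weight * err + nselec / self.dimension
        result = (value, err, nselec)
        self._cache[key] = result
        return result


def fitness(mask: np.ndarray, train_features: FeatureTable,
            eval_features: FeatureTable | None = None,
            err_weight: float = 2.0) -> float:
    """Multi-objective fitness value = err_weight * err + nselec / D.

    The LDA is trained on ``train_features`` restricted to ``mask``; err is
    the classification error on ``eval_features`` (the training set itself
    when omitted — resubstitution).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("fitness of an empty mask is undefined")
    ev = eval_features if eval_features is not None else train_features
    model = lda.fit(train_features.X[:, mask], train_features.labels)
    err = 1.0 - lda.accuracy(model.predict(ev.X[:, mask]), ev.labels) / 100.0
    return err_weight * err + mask.sum() / train_features.n_features


def initialize_swarm(config: PsoConfig, layout: FeatureLayout,
                     evaluator) -> SwarmState:
    """Seeded swarm: positions uniform(0,1), velocities uniform(-0.1, 0.1)."""
    rng = np.random.default_rng(config.seed)
    d = layout.dimension
    lo, hi = config.position_bounds
    positions = rng.uniform(lo, hi, size=(config.n_particles, d))
    velocities = rng.uniform(-1.0, 1.0, size=(config.n_particles, d)) * 0.1

    values = np.empty(config.n_particles)
    best_i, best = 0, None
    for i in range(config.n_particles):
        mask = decode_mask(positions[i], config.selection_threshold, layout)
        res = evaluator(mask)
        values[i] = res[0]
        if best is None or res[0] < best[0]:
            best, best_i = res, i
    state = SwarmState(
        positions=positions, velocities=velocities,
        pbest_positions=positions.copy(), pbest_values=values,
        gbest_position=positions[best_i].copy(), gbest_value=best[0],
        gbest_err=best[1], gbest_nselec=best[2], generation=0, rng=rng)
    state.history.append((0, best[0], best[1], best[2]))
    return state


def step_swarm(state: SwarmState, config: PsoConfig,
               evaluator, layout: FeatureLayout = FeatureLayout()) -> SwarmState:
    """One generation: velocity/position update, clamping, best-keeping.

    r1, r2 are drawn per particle *and* per dimension from the swarm's seeded
    stream.  Personal and global bests are replaced only when strictly better,
    so the global best fitness is non-increasing.
    """
    w = config.inertia(state.generation + 1)
    shape = state.positions.shape
    r1 = state.rng.uniform(0.0, 1.0, size=shape)
    r2 = state.rng.uniform(0.0, 1.0, size=shape)
    state.velocities = (
        w * state.velocities
        + config.c1 * r1 * (state.pbest_positions - state.positions)
        + config.c2 * r2 * (state.gbest_position[None, :] - state.positions))
    np.clip(state.velocities, -config.max_speed, config.max_speed,
            out=state.velocities)
    state.positions = state.positions + state.velocities
    np.clip(state.positions, *config.position_bounds, out=state.positions)

    for i in range(shape[0]):
        mask = decode_mask(state.positions[i], config.selection_threshold, layout)
        value, err, nselec = evaluator(mask)
        if value < state.pbest_values[i]:
            state.pbest_values[i] = value
            state.pbest_positions[i] = state.positions[i]
        if value < state.gbest_value:
            state.gbest_value = value
            state.gbest_err = err
            state.gbest_nselec = nselec
            state.gbest_position = state.positions[i].copy()
    state.generation += 1
    state.history.append((state.generation, state.gbest_value,
                          state.gbest_err, state.gbest_nselec))
    return state


def select_features(train: FeatureTable, config: PsoConfig = PsoConfig(),
                    layout: FeatureLayout | None = None,
                    eval_features: FeatureTable | None = None,
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Run the swarm and return (pair-closed best mask, fitness trace).

    Stops early if and only if the global-best training error reaches zero.
    With ``eval_mode='holdout'`` an internal stratified split replaces
    resubstitution when scoring candidate subsets (overfitting mitigation);
    the returned mask is still used downstream on truly held-out data.
    """
    if layout is None:
        layout = FeatureLayout(train.n_bands, train.n_filters)
    if eval_features is None and config.eval_mode == "holdout":
        train, eval_features = _stratified_split(train, config)
    evaluator = FitnessEvaluator(train, eval_features, config.err_weight)
    state = initialize_swarm(config, layout, evaluator)
    while state.generation < config.n_generations and state.gbest_err > 0.0:
        step_swarm(state, config, evaluator, layout)
    mask = decode_mask(state.gbest_position, config.selection_threshold, layout)
    trace = pd.DataFrame(state.history, columns=[
        "generation", "best_fitness", "best_err", "best_nselec"])
    return mask, trace


def _stratified_split(train: FeatureTable, config: PsoConfig,
                      ) -> tuple[FeatureTable, FeatureTable]:
    rng = np.random.default_rng(config.seed + 1)
    hold = np.zeros(train.X.shape[0], dtype=bool)
    for cls in np.unique(train.labels):
        idx = np.flatnonzero(train.labels == cls)
        n_hold = max(2, int(round(config.holdout_fraction * idx.size)))
        hold[rng.choice(idx, size=min(n_hold, idx.size - 2), replace=False)] = True
    inner = FeatureTable(train.X[~hold], train.labels[~hold],
                         train.n_bands, train.n_filters)
    held = FeatureTable(train.X[hold], train.labels[hold],
                        train.n_bands, train.n_filters)
    return inner, held
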