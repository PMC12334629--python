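"""Jellyfish Search Optimizer (JSO).

Population metaheuristic for minimizing a black-box fitness over a box
[L, U]^dim. Each "jellyfish" is a candidate vector; per iteration each one
either drifts with the ocean current (toward the incumbent best, repelled
from the population mean) or moves within the swarm, passively (a small
random step scaled by the box size) or actively (toward a random better
peer / away from a worse one). A stochastic time-control function that
decays over iterations schedules the switch from current-following to
swarm motions, and the swarm motions themselves shift from passive to
active as iterations progress. Initial positions come from a logistic
chaotic map, which spreads the population better than uniform draws.

Positions are always clipped to the box. A candidate move is accepted only
if it improves that jellyfish's fitness (greedy replacement, as in the
original algorithm); the incumbent best is tracked separately and its
fitness is non-increasing by construction. Greedy acceptance is what turns
the late-phase passive jitter into a local refinement search — without it
the swarm collapses onto the incumbent and stalls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["JsoConfig", "JsoResult", "logistic_init", "time_control",
           "ocean_current_move", "passive_move", "active_move", "optimize"]

_DEGENERATE_STARTS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class JsoConfig:
    """JSO tunables.

    population : int
        Swarm size c >= 2 (default 30).
    iterations : int
        Iteration budget N >= 1 (default 500).
    beta : float
        Logistic-map parameter, fixed at 4 (the fully chaotic regime).
    eta : float
        Ocean-current distribution coefficient (default 3).
    chi : float
        Passive-motion coefficient, fraction of the box per step (default 0.1).
    x0 : float
        Time-control threshold separating current-following from swarm
        motion (default 0.5).
    bounds : (L, U)
        Box bounds; scalars or per-dimension arrays with L < U elementwise.
    seed : int
        Seed for every random draw.
    """

    population: int = 30
    iterations: int = 500
    beta: float = 4.0
    eta: float = 3.0
    chi: float = 0.1
    x0: float = 0.5
    bounds: tuple = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.population) < 2:
            raise ValueError(f"population must be >= 2, got {self.population}")
        if int(self.iterations) < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        lo, hi = np.asarray(self.bounds[0]), np.asarray(self.bounds[1])
        if not np.all(lo < hi):
            raise ValueError("bounds must satisfy L < U elementwise")


@dataclass
class JsoResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness at the end of each iteration


def _box(config: JsoConfig, dim: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.broadcast_to(np.asarray(config.bounds[0], dtype=np.float64), (dim,)).copy()
    hi = np.broadcast_to(np.asarray(config.bounds[1], dtype=np.float64), (dim,)).copy()
    return lo, hi


def logistic_step(x: float | np.ndarray, beta: float = 4.0):
    """One logistic-map step beta * x * (1 - x)."""
    return beta * x * (1.0 - x)


def logistic_init(dim: int, config: JsoConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Chaotic logistic-map initialization of a (population x dim) matrix.

    Each dimension runs its own logistic sequence from a seeded start in
    (0, 1) excluding the degenerate fixed/periodic points {0, .25, .5, .75, 1};
    values are mapped affinely from [0, 1] onto [L, U].
    """
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = _box(config, dim)
    unit = np.empty((config.population, dim))
    for d in range(dim):
        x = rng.random()
        while any(abs(x - v) < 1e-9 for v in _DEGENERATE_STARTS):
            x = rng.random()
        for s in range(config.population):
            x = logistic_step(x, config.beta)
            unit[s, d] = x
    return lo + unit * (hi - lo)


def time_control(iteration: int, total: int, rng: np.random.Generator) -> float:
    """Decaying stochastic time-control value |(1 - it/N) * (2r - 1)| in [0, 1)."""
    return abs((1.0 - iteration / total) * (2.0 * rng.random() - 1.0))


def ocean_current_move(position, best, mean, config: JsoConfig, rng: np.random.Generator):
    """Drift with the ocean current: J + r2 * (J* - eta * r1 * mean), clipped."""
    position = np.asarray(position, dtype=np.float64)
    lo, hi = _box(config, position.size)
    trend = np.asarray(best) - config.eta * rng.random() * np.asarray(mean)
    return np.clip(position + rng.random() * trend, lo, hi)


def passive_move(position, config: JsoConfig, rng: np.random.Generator):
    """Small exploratory step around the jellyfish's own position."""
    position = np.asarray(position, dtype=np.float64)
    lo, hi = _box(config, position.size)
    return np.clip(position + config.chi * rng.random() * (hi - lo), lo, hi)


def active_move(position, other, fitness_s: float, fitness_q: float,
                config: JsoConfig, rng: np.random.Generator):
    """Step toward a better peer (or away from a worse one), clipped."""
    position = np.asarray(position, dtype=np.float64)
    other = np.asarray(other, dtype=np.float64)
    lo, hi = _box(config, position.size)
    direction = other - position if fitness_s >= fitness_q else position - other
    return np.clip(position + rng.random() * direction, lo, hi)


def optimize(fitness: Callable[[np.ndarray], float], dim: int, config: JsoConfig,
             batch_fitness: Callable[[np.ndarray], np.ndarray] | None = None) -> JsoResult:
    """Run JSO, minimizing ``fitness`` over [L, U]^dim.

    ``batch_fitness`` optionally evaluates a (population x dim) matrix at
    once (used by the segmenter, whose forward pass vectorizes over
    candidates); results are identical to per-vector evaluation.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    c, n_iter = cfg.population, cfg.iterations

    def _eval_one(v: np.ndarray) -> float:
        f = float(fitness(v))
        if not np.isfinite(f):
            raise FloatingPointError(f"non-finite fitness {f} at position {v}")
        return f

    def _eval_all(pos: np.ndarray) -> np.ndarray:
        if batch_fitness is not None:
            f = np.asarray(batch_fitness(pos), dtype=np.float64)
            if not np.all(np.isfinite(f)):
                bad = pos[np.argmax(~np.isfinite(f))]
                raise FloatingPointError(f"non-finite fitness at position {bad}")
            return f
        return np.array([_eval_one(v) for v in pos])

    positions = logistic_init(dim, cfg, rng)
    fitnesses = _eval_all(positions)
    best_idx = int(np.argmin(fitnesses))
    best_pos = positions[best_idx].copy()
    best_fit = float(fitnesses[best_idx])

    history = np.empty(n_iter)
    for it in range(1, n_iter + 1):
        mean = positions.mean(axis=0)
        candidates = np.empty_like(positions)
        for s in range(c):
            xi = time_control(it, n_iter, rng)
            if xi >= cfg.x0:
                new = ocean_current_move(positions[s], best_pos, mean, cfg, rng)
            elif rng.random() > (1.0 - it / n_iter):
                new = passive_move(positions[s], cfg, rng)
            else:
                q = int(rng.integers(c - 1))
                q = q + 1 if q >= s else q
                new = active_move(positions[s], positions[q], fitnesses[s], fitnesses[q], cfg, rng)
            candidates[s] = new
        cand_fit = _eval_all(candidates)
        accepted = cand_fit < fitnesses
        positions[accepted] = candidates[accepted]
        fitnesses[accepted] = cand_fit[accepted]
        it_best = int(np.argmin(fitnesses))
        if fitnesses[it_best] < best_fit:
            best_fit = float(fitnesses[it_best])
            best_pos = positions[it_best].copy()
        history[it - 1] = best_fit
    return JsoResult(best_pos, best_fit, history)


def history_to_csv(result: JsoResult, path) -> None:
    """Export the per-iteration incumbent-best curve as CSV."""
    import pandas as pd

    pd.DataFrame(
        {"iteration": np.arange(1, result.history.size + 1), "best_fitness": result.history}
    ).to_csv(path, index=False)
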