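"""Influence-strength calibration by random-restart hill climbing.

The 36 free strengths (marriage/household/friendship x 4 behaviours x 3
levels; workplace is fixed at zero) are fitted so simulated incidence
matches observed rates.  Fitness is the mean, over a few simulations, of
the summed absolute difference between simulated and observed rates per
(age group, sex) cell.  Hill climbing proposes +/-U(0, 0.05) perturbations
of all entries, accepts only strict improvements, and restarts from a fresh
random point with a probability that grows with consecutive failures.  The
search runs in rounds: each round re-centres the sampling range to the
incumbent best +/- a refinement window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .engine import SimulationConfig, run_simulation
from .parameters import AGE_GROUPS, InfluenceMatrix, ParameterSet, SEXES

PERTURB_SCALE = 0.05
RESTART_INCREMENT = 0.02
RESTART_CAP = 0.5


@dataclass
class SearchState:
    current: np.ndarray
    current_fitness: float
    best: np.ndarray
    best_fitness: float
    consecutive_failures: int = 0
    restart_probability: float = 0.0


@dataclass
class CalibrationResult:
    best: np.ndarray
    best_fitness: float
    evaluations: int          # proposal evaluations (searches x iterations x rounds)
    fitness_history: list[float] = field(default_factory=list)  # best-so-far per search

    @property
    def matrix(self) -> InfluenceMatrix:
        return InfluenceMatrix.from_free_vector(self.best)


def perturb(
    matrix: InfluenceMatrix | np.ndarray,
    rng: np.random.Generator,
    scale: float = PERTURB_SCALE,
):
    """Move every free entry by an independent +/-U(0, scale), clamped to [0, 1].

    Accepts either an InfluenceMatrix (the workplace row is untouched) or a
    bare vector; returns the same type.
    """
    is_matrix = isinstance(matrix, InfluenceMatrix)
    vec = matrix.free_vector if is_matrix else np.asarray(matrix, dtype=float).copy()
    signs = rng.choice([-1.0, 1.0], size=vec.size)
    vec = np.clip(vec + signs * rng.uniform(0.0, scale, size=vec.size), 0.0, 1.0)
    if is_matrix:
        out = InfluenceMatrix.from_free_vector(vec)
        out.data[3] = matrix.data[3]  # preserve workplace row
        return out
    return vec


def observed_to_array(observed: pd.DataFrame) -> np.ndarray:
    """Observed rates as a (12 age groups, 2 sexes) array."""
    arr = np.full((len(AGE_GROUPS), len(SEXES)), np.nan)
    for _, row in observed.iterrows():
        arr[AGE_GROUPS.index(row["age_group"]), SEXES.index(row["sex"])] = row["rate"]
    if np.isnan(arr).any():
        raise ValueError("observed rates do not cover all 12 age groups x 2 sexes")
    return arr


def simulated_rates(
    matrix: InfluenceMatrix, params: ParameterSet, config: SimulationConfig, seed: int
) -> np.ndarray:
    """Rates per (age group, sex) from one simulation under ``matrix``.

    Strata with zero person-years report rate 0, so empty cells count their
    full observed rate as error rather than being silently dropped.
    """
    p = params.copy()
    p.influence = matrix
    report = run_simulation(config, p, seed=seed)
    rates = report.by_stratum["rate"].to_numpy(float).reshape(len(AGE_GROUPS), len(SEXES))
    return np.nan_to_num(rates, nan=0.0)


def fitness(
    matrix: InfluenceMatrix,
    observed: pd.DataFrame | np.ndarray,
    params: ParameterSet | None,
    config: SimulationConfig | None,
    n_sims: int,
    rng: np.random.Generator,
    simulate: Callable[[InfluenceMatrix, int], np.ndarray] | None = None,
) -> float:
    """Mean over ``n_sims`` runs of sum |simulated - observed| over 24 cells.

    ``simulate(matrix, seed) -> (12, 2) rates`` may be injected (e.g. a stub
    or surrogate); by default it runs the full simulator with ``params`` and
    ``config``.
    """
    obs = observed if isinstance(observed, np.ndarray) else observed_to_array(observed)
    if simulate is None:
        if params is None or config is None:
            raise ValueError("params and config are required without a simulate callable")
        simulate = lambda m, s: simulated_rates(m, params, config, s)
    total = 0.0
    for _ in range(n_sims):
        sim = simulate(matrix, int(rng.integers(2**31)))
        total += float(np.abs(sim - obs).sum())
    return total / n_sims


def hill_climb(
    objective: Callable[[np.ndarray], float],
    init: np.ndarray,
    iterations: int,
    restart_range: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    perturb_scale: float = PERTURB_SCALE,
    restart_increment: float = RESTART_INCREMENT,
    restart_cap: float = RESTART_CAP,
) -> tuple[np.ndarray, float, SearchState, int]:
    """Accept-if-better local search with failure-driven random restarts.

    Each iteration proposes either a fresh uniform draw from
    ``restart_range`` (with the current restart probability) or a
    perturbation of the incumbent; the proposal is adopted only if its
    objective strictly improves on the incumbent's.  The restart probability
    is ``min(restart_increment x consecutive failures, restart_cap)`` and
    resets on improvement.  Returns (best, best objective, final state,
    number of proposal evaluations).
    """
    lo, hi = restart_range
    x = np.asarray(init, dtype=float).copy()
    fx = float(objective(x))
    state = SearchState(current=x, current_fitness=fx, best=x.copy(), best_fitness=fx)
    evaluations = 0
    for _ in range(iterations):
        if rng.random() < state.restart_probability:
            cand = rng.uniform(lo, hi)
        else:
            cand = perturb(state.current, rng, scale=perturb_scale)
        fc = float(objective(cand))
        evaluations += 1
        if fc < state.current_fitness:
            state.current, state.current_fitness = cand, fc
            state.consecutive_failures = 0
        else:
            state.consecutive_failures += 1
        state.restart_probability = min(
            restart_increment * state.consecutive_failures, restart_cap
        )
        if fc < state.best_fitness:
            state.best, state.best_fitness = cand.copy(), fc
    return state.best, state.best_fitness, state, evaluations


def random_restart_search(
    objective: Callable[[np.ndarray], float],
    dim: int,
    searches: int,
    iterations: int,
    rounds: int,
    window: float,
    rng: np.random.Generator,
    global_range: tuple[float, float] = (0.0, 1.0),
) -> CalibrationResult:
    """Multi-round random-restart hill climbing over ``[0, 1]^dim``.

    Round 1 draws initial points from the global range; each later round
    re-centres the sampling range to the incumbent best +/- ``window``
    (clamped to [0, 1]).  Total proposal evaluations equal
    ``searches x iterations x rounds``.
    """
    lo = np.full(dim, float(global_range[0]))
    hi = np.full(dim, float(global_range[1]))
    best: np.ndarray | None = None
    best_fit = np.inf
    evaluations = 0
    history: list[float] = []

    for _ in range(rounds):
        for _ in range(searches):
            init = rng.uniform(lo, hi)
            b, f, _state, ev = hill_climb(
                objective, init, iterations, (lo, hi), rng
            )
            evaluations += ev
            if f < best_fit:
                best, best_fit = b.copy(), f
            history.append(best_fit)
        lo = np.clip(best - window, 0.0, 1.0)
        hi = np.clip(best + window, 0.0, 1.0)

    return CalibrationResult(
        best=best, best_fitness=best_fit, evaluations=evaluations, fitness_history=history
    )


def calibrate_influence(
    params: ParameterSet,
    observed: pd.DataFrame,
    config: SimulationConfig,
    searches: int = 500,
    iterations: int = 100,
    rounds: int = 5,
    window: float = 0.1,
    n_sims: int = 5,
    seed: int = 0,
    simulate: Callable[[InfluenceMatrix, int], np.ndarray] | None = None,
) -> tuple[InfluenceMatrix, CalibrationResult]:
    """Fit the 36 free influence strengths against observed incidence rates.

    Defaults match the full calibration protocol (500 searches x 100
    iterations x 5 rounds = 250,000 parameter sets, fitness averaged over 5
    simulations); pass smaller values for reduced-scale runs.  The returned
    matrix carries a zero workplace row.
    """
    rng = np.random.default_rng(seed)
    obs = observed_to_array(observed)

    def objective(vec: np.ndarray) -> float:
        return fitness(
            InfluenceMatrix.from_free_vector(vec),
            obs, params, config, n_sims, rng, simulate=simulate,
        )

    result = random_restart_search(
        objective, dim=36, searches=searches, iterations=iterations,
        rounds=rounds, window=window, rng=rng,
    )
    return result.matrix, result
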