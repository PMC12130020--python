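"""Genetic-algorithm outer loop for fitting genome parameters.

A population of parameter vectors (uniformly initialized within bounds)
evolves by tournament selection (size 3), uniform crossover (per-gene rate
0.5), per-gene Gaussian mutation (sigma = 10% of the bound width, rate
0.2), clipping to bounds, and elitism of one: the best individual always
survives unchanged, so the best-fitness trace is non-decreasing.  Fitness
is maximized.  An individual whose fitness callable raises is scored at
``-inf`` and the run continues.  Runs are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["GAConfig", "GARunState", "run_ga", "convergence_stats"]

FAILED_FITNESS = -np.inf


@dataclass
class GAConfig:
    pop_size: int = 100
    generations: int = 100
    tournament_size: int = 3
    crossover_rate: float = 0.5     # per-gene swap probability
    mutation_rate: float = 0.2      # per-gene mutation probability
    mutation_sigma: float = 0.1     # fraction of bound width
    elitism: int = 1


@dataclass
class GARunState:
    """Final population and per-generation history of one GA run."""

    names: list
    population: np.ndarray              # (pop, n_params)
    fitness: np.ndarray                 # (pop,)
    history_best: np.ndarray            # (generations + 1,)
    history_median: np.ndarray
    seed: Optional[int] = None
    best_per_generation: list = field(default_factory=list)

    @property
    def best_genome_values(self) -> dict:
        i = int(np.argmax(self.fitness))
        return dict(zip(self.names, self.population[i]))

    @property
    def best_fitness(self) -> float:
        return float(np.max(self.fitness))


def _evaluate(fitness_fn: Callable, names, pop: np.ndarray) -> np.ndarray:
    out = np.empty(len(pop))
    for i, row in enumerate(pop):
        try:
            f = fitness_fn(dict(zip(names, row)))
            out[i] = f if np.isfinite(f) else FAILED_FITNESS
        except Exception:
            out[i] = FAILED_FITNESS
    return out


def run_ga(bounds: dict, fitness_fn: Callable, pop_size: int = 100,
           generations: int = 100, seed: Optional[int] = None,
           config: Optional[GAConfig] = None) -> GARunState:
    """Maximize ``fitness_fn`` (dict of named parameters -> float).

    ``bounds`` maps parameter names to closed intervals; initialization is
    uniform within them.  Returns the full run state including the
    non-decreasing best-fitness history.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    cfg = config or GAConfig()
    cfg.pop_size, cfg.generations = pop_size, generations
    rng = np.random.default_rng(seed)
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    width = hi - lo
    n = len(names)

    pop = lo + rng.random((pop_size, n)) * width
    fit = _evaluate(fitness_fn, names, pop)
    hist_best = [np.max(fit)]
    hist_med = [np.median(fit)]
    best_rows = [pop[int(np.argmax(fit))].copy()]

    for _ in range(generations):
        order = np.argsort(fit)[::-1]
        elite = pop[order[:cfg.elitism]].copy()
        elite_fit = fit[order[:cfg.elitism]].copy()

        # tournament selection of parents
        idx = rng.integers(0, pop_size, size=(pop_size, cfg.tournament_size))
        winners = idx[np.arange(pop_size), np.argmax(fit[idx], axis=1)]
        parents = pop[winners]

        # uniform crossover of consecutive pairs
        children = parents.copy()
        for i in range(0, pop_size - 1, 2):
            swap = rng.random(n) < cfg.crossover_rate
            a, b = children[i].copy(), children[i + 1].copy()
            children[i, swap], children[i + 1, swap] = b[swap], a[swap]

        # Gaussian mutation, clipped to bounds
        mutate = rng.random((pop_size, n)) < cfg.mutation_rate
        noise = rng.normal(0.0, cfg.mutation_sigma, size=(pop_size, n)) * width
        children = np.clip(children + mutate * noise, lo, hi)

        children[:cfg.elitism] = elite
        child_fit = _evaluate(fitness_fn, names, children)
        child_fit[:cfg.elitism] = elite_fit

        pop, fit = children, child_fit
        hist_best.append(max(np.max(fit), hist_best[-1]))
        hist_med.append(np.median(fit))
        best_rows.append(pop[int(np.argmax(fit))].copy())

    return GARunState(names=names, population=pop, fitness=fit,
                      history_best=np.array(hist_best),
                      history_median=np.array(hist_med),
                      seed=seed, best_per_generation=best_rows)


def convergence_stats(trials: Sequence[GARunState]) -> dict:
    """Per-generation median, quartiles and min-max over repeated trials."""
    if not trials:
        raise ValueError("need at least one trial")
    traces = np.stack([t.history_best for t in trials])    # (trials, gens+1)
    return {
        "median": np.median(traces, axis=0),
        "q1": np.percentile(traces, 25, axis=0),
        "q3": np.percentile(traces, 75, axis=0),
        "min": traces.min(axis=0),
        "max": traces.max(axis=0),
        "n_trials": len(trials),
    }
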