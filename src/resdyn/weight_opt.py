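"""Genetic-algorithm fitting of augmented-heuristic weights.

The augmented greedy policies score sites with per-habitat weights
``lambda_1..lambda_J`` and a cost weight ``lambda_c``.  Good weights depend on
the landscape (relative habitat rarity, conversion pressure, BLM), so they
are fitted by maximizing the policy's simulated performance: the fitness of a
weight vector is minus its Monte-Carlo expected extended cost on a fixed set
of pre-sampled scenarios.  Using one common scenario set for every fitness
call removes most of the comparison noise between candidate vectors.

Weights live on a discrete grid (default 0.2, 0.4, ..., 2.2) and are searched
by a small generational GA with tournament selection, uniform crossover,
per-gene grid mutation and single-individual elitism.  The all-ones vector —
which reduces the augmented policy to its plain counterpart — is always
seeded into the initial population, so the fitted policy can never do worse
than the plain heuristic on the training scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import BudgetModel, Scenario, estimate_eec, sample_scenarios
from .landscape import Landscape
from .policies import GreedyPolicy, WeightVector

__all__ = ["GAParams", "DEFAULT_GRID", "fitness", "optimize_weights"]

DEFAULT_GRID: tuple[float, ...] = tuple(round(0.2 * k, 10) for k in range(1, 12))


@dataclass(frozen=True)
class GAParams:
    population: int = 40
    generations: int = 25
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    tournament: int = 3
    grid: tuple[float, ...] = DEFAULT_GRID
    n_mc: int = 200
    seed: int = 0
    horizon_cap: int = 500

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if any(g <= 0 for g in self.grid):
            raise ValueError("grid values must be > 0")


def _heuristic_kind(heuristic: str) -> str:
    if heuristic not in ("richness", "rarity"):
        raise ValueError(f"heuristic must be 'richness' or 'rarity', got {heuristic!r}")
    return heuristic


def fitness(
    weights: WeightVector,
    landscape: Landscape,
    heuristic: str,
    budget_model: BudgetModel,
    n_mc: int = 200,
    seed: int = 0,
    scenarios: Sequence[Scenario] | None = None,
    horizon_cap: int = 500,
) -> float:
    """Minus the Monte-Carlo EEC of the augmented policy with these weights.

    Higher is better.  With the same seed (or an explicit scenario set) the
    value is exactly reproducible, so fitness differences between weight
    vectors reflect the weights, not the sampling.
    """
    policy = GreedyPolicy(_heuristic_kind(heuristic), weights)
    est = estimate_eec(
        policy, landscape, budget_model,
        n_scenarios=n_mc, seed=seed, horizon_cap=horizon_cap, scenarios=scenarios,
    )
    return -est.mean


def optimize_weights(
    landscape: Landscape,
    heuristic: str,
    budget_model: BudgetModel,
    ga: GAParams | None = None,
) -> tuple[WeightVector, list[float]]:
    """Fit augmented-heuristic weights by grid-constrained GA.

    Returns the best-ever weight vector and the per-generation best-fitness
    trace (monotone non-decreasing thanks to elitism).
    """
    ga = ga or GAParams()
    kind = _heuristic_kind(heuristic)
    n_genes = landscape.n_targets + 1  # lambda_1..J plus lambda_c
    grid = np.asarray(ga.grid, dtype=float)
    rng = np.random.default_rng(ga.seed)
    scenarios = sample_scenarios(
        landscape, budget_model, ga.n_mc, ga.seed, ga.horizon_cap
    )

    cache: dict[tuple[int, ...], float] = {}

    def evaluate(genome: tuple[int, ...]) -> float:
        val = cache.get(genome)
        if val is None:
            wv = WeightVector(tuple(grid[list(genome[:-1])]), float(grid[genome[-1]]))
            val = fitness(
                wv, landscape, kind, budget_model, scenarios=scenarios,
                horizon_cap=ga.horizon_cap,
            )
            cache[genome] = val
        return val

    ones_gene = int(np.argmin(np.abs(grid - 1.0)))
    population: list[tuple[int, ...]] = [(ones_gene,) * n_genes]
    while len(population) < ga.population:
        population.append(tuple(rng.integers(0, len(grid), n_genes)))

    fits = [evaluate(g) for g in population]
    best_idx = int(np.argmax(fits))
    best_genome, best_fit = population[best_idx], fits[best_idx]
    trace = [best_fit]

    def tournament() -> tuple[int, ...]:
        picks = rng.integers(0, len(population), ga.tournament)
        winner = max(picks, key=lambda i: fits[i])
        return population[winner]

    for _ in range(ga.generations):
        offspring: list[tuple[int, ...]] = [best_genome]  # elitism
        while len(offspring) < ga.population:
            a, b = tournament(), tournament()
            if rng.random() < ga.crossover_rate:
                child = tuple(
                    a[i] if rng.random() < 0.5 else b[i] for i in range(n_genes)
                )
            else:
                child = a
            child = tuple(
                int(rng.integers(0, len(grid))) if rng.random() < ga.mutation_rate else g
                for g in child
            )
            offspring.append(child)
        population = offspring
        fits = [evaluate(g) for g in population]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_genome, best_fit = population[gen_best], fits[gen_best]
        trace.append(best_fit)

    best = WeightVector(
        tuple(grid[list(best_genome[:-1])]), float(grid[best_genome[-1]])
    )
    return best, trace
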