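"""Scenario simulation and Monte-Carlo policy evaluation.

A *scenario* pre-samples, independently of any policy, the period at whose
end each site would be converted if still unprotected, together with the
yearly budget draws.  Policies evaluated on the same scenario therefore see
identical land-conversion trajectories (common random numbers), which makes
policy comparisons far less noisy than independent simulation.

The expected extended cost (EEC) of a policy is the expectation of the final
network's extended cost over conversion and budget randomness; here it is
estimated by averaging rollouts over seeded scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .landscape import Landscape, ReserveState

__all__ = [
    "BudgetModel",
    "Scenario",
    "EECEstimate",
    "RolloutResult",
    "PolicyContractError",
    "sample_scenario",
    "rollout",
    "estimate_eec",
]

# A policy is any callable (state, effective_budget, period, landscape) -> set of ids.
PolicyFn = Callable[[ReserveState, float, int, Landscape], frozenset]


class PolicyContractError(RuntimeError):
    """A policy returned a purchase that is unavailable or unaffordable."""


class BudgetModel:
    """Yearly budget: a constant, or a finite discrete distribution."""

    def __init__(self, amounts: Sequence[float], probs: Sequence[float]):
        self.amounts = np.asarray(amounts, dtype=float)
        self.probs = np.asarray(probs, dtype=float)
        if np.any(self.amounts <= 0):
            raise ValueError("budget amounts must be > 0")
        if len(self.amounts) != len(self.probs) or not math.isclose(
            float(self.probs.sum()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("budget probabilities must match amounts and sum to 1")

    @classmethod
    def constant(cls, amount: float) -> "BudgetModel":
        return cls([amount], [1.0])

    @classmethod
    def discrete(cls, amounts: Sequence[float], probs: Sequence[float]) -> "BudgetModel":
        return cls(amounts, probs)

    @property
    def is_constant(self) -> bool:
        return len(self.amounts) == 1

    def mean(self) -> float:
        return float(self.amounts @ self.probs)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.is_constant:
            return np.full(size, self.amounts[0])
        return rng.choice(self.amounts, size=size, p=self.probs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BudgetModel):
            return NotImplemented
        return np.array_equal(self.amounts, other.amounts) and np.array_equal(
            self.probs, other.probs
        )


@dataclass(frozen=True)
class Scenario:
    """Policy-independent draw of conversion times and budgets.

    ``conversion_time[s]`` is the first period at whose end site ``s`` is
    converted if still unreserved (``math.inf`` if never within the horizon).
    """

    conversion_time: dict[int, float]
    budgets: tuple[float, ...]
    seed: int

    @property
    def horizon(self) -> int:
        return len(self.budgets)


@dataclass(frozen=True)
class RolloutResult:
    network: frozenset[int]
    extended_cost: float
    periods: int
    spent: float
    leftover: float
    boundary: float
    targets_met: bool


@dataclass(frozen=True)
class EECEstimate:
    """Monte-Carlo EEC with sampling error and summary behaviour."""

    mean: float
    stderr: float
    n_scenarios: int
    target_frequency: float
    mean_sites: float = math.nan
    mean_boundary: float = math.nan
    mean_periods: float = math.nan


def sample_scenario(
    landscape: Landscape,
    budget_model: BudgetModel,
    seed: int,
    horizon_cap: int = 500,
) -> Scenario:
    """Draw one scenario: geometric conversion times and i.i.d. budgets.

    A site with conversion probability ``mu`` survives each period with
    probability ``1 - mu``; its conversion time is geometric with success
    ``mu`` (infinite when ``mu = 0``), truncated at ``horizon_cap``.
    """
    if horizon_cap < 1:
        raise ValueError("horizon_cap must be >= 1")
    rng = np.random.default_rng(seed)
    times: dict[int, float] = {}
    for site in landscape.sites:
        if site.mu <= 0.0:
            times[site.id] = math.inf
        elif site.mu >= 1.0:
            times[site.id] = 1.0
        else:
            t = float(rng.geometric(site.mu))
            times[site.id] = t if t <= horizon_cap else math.inf
    budgets = tuple(float(b) for b in budget_model.sample(rng, horizon_cap))
    return Scenario(conversion_time=times, budgets=budgets, seed=seed)


def rollout(policy: PolicyFn, scenario: Scenario, landscape: Landscape) -> RolloutResult:
    """Apply ``policy`` period by period on one pre-sampled scenario.

    Each period: the effective budget is the fresh draw plus all unspent
    carryover; the policy purchases a feasible set; purchased sites can no
    longer convert; then surviving unreserved sites whose conversion time is
    the current period are removed.  The run ends when all targets are met,
    no sites remain available, or the scenario horizon is exhausted.
    """
    available = set(landscape.site_ids - landscape.initial_reserve)
    reserved = set(landscape.initial_reserve)
    carry = 0.0
    spent = 0.0
    periods = 0
    met = landscape.targets_met(reserved)

    for t in range(1, scenario.horizon + 1):
        if met or not available:
            break
        periods = t
        budget = scenario.budgets[t - 1] + carry
        state = ReserveState(frozenset(available), frozenset(reserved))
        purchase = frozenset(policy(state, budget, t, landscape))
        if not purchase <= state.available:
            raise PolicyContractError(
                f"policy purchased unavailable sites {sorted(purchase - state.available)}"
            )
        cost = landscape.total_cost(purchase)
        if cost > budget + 1e-9:
            raise PolicyContractError(
                f"policy overspent: cost {cost} exceeds effective budget {budget}"
            )
        reserved |= purchase
        available -= purchase
        carry = budget - cost
        spent += cost
        met = landscape.targets_met(reserved)
        # end-of-period conversions
        available = {s for s in available if scenario.conversion_time[s] > t}

    network = frozenset(reserved)
    return RolloutResult(
        network=network,
        extended_cost=landscape.extended_cost(network),
        periods=periods,
        spent=spent,
        leftover=carry,
        boundary=landscape.boundary(network),
        targets_met=met,
    )


def scenario_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent scenario seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def sample_scenarios(
    landscape: Landscape,
    budget_model: BudgetModel,
    n: int,
    seed: int,
    horizon_cap: int = 500,
) -> list[Scenario]:
    return [
        sample_scenario(landscape, budget_model, s, horizon_cap)
        for s in scenario_seeds(seed, n)
    ]


def estimate_eec(
    policy: PolicyFn,
    landscape: Landscape,
    budget_model: BudgetModel,
    n_scenarios: int = 1000,
    seed: int = 0,
    horizon_cap: int = 500,
    scenarios: Sequence[Scenario] | None = None,
    return_rollouts: bool = False,
):
    """Monte-Carlo estimate of a policy's expected extended cost.

    ``scenarios`` may be supplied explicitly to share draws across policies;
    otherwise ``n_scenarios`` scenarios are generated from ``seed``.
    """
    if scenarios is None:
        if n_scenarios < 1:
            raise ValueError("n_scenarios must be >= 1")
        scenarios = sample_scenarios(landscape, budget_model, n_scenarios, seed, horizon_cap)
    results = [rollout(policy, sc, landscape) for sc in scenarios]
    costs = np.array([r.extended_cost for r in results])
    n = len(costs)
    stderr = float(costs.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    estimate = EECEstimate(
        mean=float(costs.mean()),
        stderr=stderr,
        n_scenarios=n,
        target_frequency=float(np.mean([r.targets_met for r in results])),
        mean_sites=float(np.mean([len(r.network) for r in results])),
        mean_boundary=float(np.mean([r.boundary for r in results])),
        mean_periods=float(np.mean([r.periods for r in results])),
    )
    if return_rollouts:
        return estimate, results
    return estimate
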