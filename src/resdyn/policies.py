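"""Decision rules for sequential reserve assembly.

All policies share one contract: given the current :class:`ReserveState`, the
effective budget for the period, the period index and the landscape, return a
feasible purchase (a subset of the available sites whose total cost fits the
budget).

Implemented rules:

* ``cheapest`` — buy the cheapest available sites until the budget runs out.
* ``greedy-rich`` / ``greedy-rar`` — iteratively buy the highest-scoring
  affordable site, where the score is a per-habitat richness or rarity
  desirability divided by the marginal extended cost of adding the site.
* ``aug-rich`` / ``aug-rar`` — the same scores with per-habitat weights
  ``lambda_1..lambda_J`` (and a cost weight ``lambda_c``), typically fitted by
  the genetic optimizer in :mod:`resdyn.weight_opt`.
* ``dyn-minset`` — re-solve the static minimum-set problem every period with
  already-reserved sites locked in, order the solution by expected effective
  abundance under conversion risk, and buy the longest affordable prefix.

Scores are positive desirabilities and are maximized; the richness/rarity
rewards appear in cost-sign (negated) form in the source formulation, which
does not change the induced ranking.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .landscape import Landscape, ReserveState
from .ordering import optimal_ordering
from .static_solver import SAParams, anneal

__all__ = [
    "WeightVector",
    "richness_score",
    "rarity_score",
    "greedy_step",
    "cheapest_first_step",
    "dynamic_minset_step",
    "CheapestFirst",
    "GreedyPolicy",
    "DynamicMinSet",
    "make_policy",
    "POLICY_NAMES",
]


@dataclass(frozen=True)
class WeightVector:
    """Habitat weights ``lambda_1..lambda_J`` plus the cost weight ``lambda_c``.

    Scores use the ratios ``lambda_j / lambda_c``, so uniformly rescaling all
    weights (including ``lambda_c``) leaves every ranking unchanged.
    """

    lambdas: tuple[float, ...]
    lambda_c: float = 1.0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lambdas) or self.lambda_c <= 0:
            raise ValueError("all weights must be > 0")
        object.__setattr__(self, "lambdas", tuple(float(l) for l in self.lambdas))

    def ratios(self, n_targets: int) -> tuple[float, ...]:
        if len(self.lambdas) != n_targets:
            raise ValueError(
                f"{len(self.lambdas)} habitat weights for {n_targets} targets"
            )
        return tuple(l / self.lambda_c for l in self.lambdas)


def _epsilon(landscape: Landscape) -> float:
    # clamp for degenerate (<= 0) marginal costs: a site that plugs a boundary
    # hole can make c + BLM*delta_boundary non-positive; such sites should be
    # strongly favoured, not crash the ranking.
    return 1e-9 * max(float(landscape.cost_array.mean()), 1e-12)


def _delta_boundary(landscape: Landscape, sid: int, network: set | frozenset) -> float:
    site = landscape._sites_by_id[sid]
    d = site.perimeter
    for other, length in landscape._adjacency[sid]:
        if other in network:
            d -= 2.0 * length
    return d


def _weight_ratios(weights: WeightVector | None, n_targets: int) -> tuple[float, ...]:
    if weights is None:
        return (1.0,) * n_targets
    return weights.ratios(n_targets)


def _site_score(
    kind: str,
    sid: int,
    landscape: Landscape,
    reserved: frozenset | set,
    res_abund: np.ndarray,
    rarity_denoms: Sequence[float] | None,
    ratios: Sequence[float],
    eps: float,
) -> float:
    site = landscape._sites_by_id[sid]
    denom = max(eps, site.cost + landscape.blm * _delta_boundary(landscape, sid, reserved))
    targets = landscape.targets
    total = 0.0
    for col in range(landscape.n_targets):
        if kind == "richness":
            if res_abund[col] < targets[col] - 1e-12:
                term = site.habitat[col] / (targets[col] * denom) if targets[col] > 0 else 1.0
            else:
                term = 1.0
        else:  # rarity
            r = rarity_denoms[col]
            if r > 0:
                ea = min(float(targets[col]), float(res_abund[col]) + site.habitat[col])
                term = (ea / r) / denom
            else:
                term = 0.0
        total += ratios[col] * term
    return total


def richness_score(
    site_id: int,
    state: ReserveState,
    landscape: Landscape,
    weights: WeightVector | None = None,
) -> float:
    """Richness desirability of one available site (higher = buy sooner).

    For each unmet habitat the site contributes its habitat amount relative
    to the target, per unit of marginal extended cost; met habitats
    contribute a rank-neutral constant 1.
    """
    if site_id not in state.available:
        raise ValueError(f"site {site_id} is not available in this state")
    res_abund = landscape.abundance_vector(state.reserved)
    return _site_score(
        "richness", site_id, landscape, state.reserved, res_abund, None,
        _weight_ratios(weights, landscape.n_targets), _epsilon(landscape),
    )


def rarity_score(
    site_id: int,
    state: ReserveState,
    landscape: Landscape,
    weights: WeightVector | None = None,
) -> float:
    """Rarity desirability: effective abundance of the would-be network,
    relative to how much of each habitat is left among available sites,
    per unit of marginal extended cost.  Habitats that are scarce in the
    remaining landscape dominate the score."""
    if site_id not in state.available:
        raise ValueError(f"site {site_id} is not available in this state")
    res_abund = landscape.abundance_vector(state.reserved)
    denoms = landscape.abundance_vector(state.available)
    return _site_score(
        "rarity", site_id, landscape, state.reserved, res_abund, denoms,
        _weight_ratios(weights, landscape.n_targets), _epsilon(landscape),
    )


def greedy_step(
    state: ReserveState,
    effective_budget: float,
    landscape: Landscape,
    kind: str = "richness",
    weights: WeightVector | None = None,
) -> frozenset[int]:
    """One period of a greedy policy.

    Repeatedly buy the affordable site with the highest score, updating the
    working reserve (and hence boundary deltas, effective abundances and the
    remaining-habitat denominators) after every purchase, until no site is
    affordable or all targets are met.  Ties break toward the smallest id.
    """
    if kind not in ("richness", "rarity"):
        raise ValueError(f"unknown greedy score kind {kind!r}")
    ratios = _weight_ratios(weights, landscape.n_targets)
    eps = _epsilon(landscape)
    targets = landscape.targets
    reserved = set(state.reserved)
    avail = set(state.available)
    res_abund = landscape.abundance_vector(reserved)
    remaining = float(effective_budget)
    chosen: set[int] = set()

    while np.any(res_abund < targets - 1e-12):
        denoms = landscape.abundance_vector(avail) if kind == "rarity" else None
        best_id, best_score = None, -1.0
        for sid in sorted(avail):
            if landscape._sites_by_id[sid].cost > remaining + 1e-9:
                continue
            s = _site_score(kind, sid, landscape, reserved, res_abund, denoms, ratios, eps)
            if s > best_score + 1e-12:
                best_id, best_score = sid, s
        if best_id is None:
            break
        chosen.add(best_id)
        reserved.add(best_id)
        avail.discard(best_id)
        site = landscape._sites_by_id[best_id]
        res_abund = res_abund + np.asarray(site.habitat[: landscape.n_targets])
        remaining -= site.cost
    return frozenset(chosen)


def cheapest_first_step(
    state: ReserveState,
    effective_budget: float,
    landscape: Landscape,
) -> frozenset[int]:
    """Buy available sites in ascending cost order (ties by id) while the
    budget allows and some target is still unmet."""
    reserved = set(state.reserved)
    res_abund = landscape.abundance_vector(reserved)
    remaining = float(effective_budget)
    chosen: set[int] = set()
    for sid in sorted(state.available, key=lambda s: (landscape._sites_by_id[s].cost, s)):
        if not np.any(res_abund < landscape.targets - 1e-12):
            break
        site = landscape._sites_by_id[sid]
        if site.cost > remaining + 1e-9:
            break
        chosen.add(sid)
        remaining -= site.cost
        res_abund = res_abund + np.asarray(site.habitat[: landscape.n_targets])
    return frozenset(chosen)


def dynamic_minset_step(
    state: ReserveState,
    effective_budget: float,
    landscape: Landscape,
    sa_params: SAParams | None = None,
    criterion: str = "utilitarian",
    m_B: float | None = None,
) -> frozenset[int]:
    """One period of the dynamic minimum-set policy.

    Re-solve the static problem from scratch with the current reserve locked
    in, order the new solution sites by expected effective abundance (using
    ``m_B`` as the reference yearly budget), and purchase the longest
    affordable strict prefix of that sequence.
    """
    if not state.available:
        return frozenset()
    solution = anneal(landscape, state.available, locked=state.reserved, params=sa_params)
    plan = sorted(solution - state.reserved)
    if not plan:
        return frozenset()
    base = landscape.abundance_vector(state.reserved)
    ref_budget = m_B if m_B is not None else max(float(effective_budget), 1e-9)
    seq = optimal_ordering(plan, landscape, criterion, ref_budget, base_abundance=base)
    remaining = float(effective_budget)
    buy: list[int] = []
    for sid in seq.sites:
        c = landscape._sites_by_id[sid].cost
        if c > remaining + 1e-9:
            break  # strict prefix: no skipping ahead to cheaper later sites
        buy.append(sid)
        remaining -= c
    return frozenset(buy)


# -- policy objects (uniform contract) --------------------------------------


class CheapestFirst:
    """Cheapest-sites-first baseline."""

    def __call__(self, state, budget, period, landscape):
        return cheapest_first_step(state, budget, landscape)


class GreedyPolicy:
    """Greedy richness/rarity policy, optionally weight-augmented."""

    def __init__(self, kind: str = "richness", weights: WeightVector | None = None):
        if kind not in ("richness", "rarity"):
            raise ValueError(f"unknown greedy score kind {kind!r}")
        self.kind = kind
        self.weights = weights

    def __call__(self, state, budget, period, landscape):
        return greedy_step(state, budget, landscape, self.kind, self.weights)


def _state_seed(base_seed: int, state: ReserveState) -> int:
    key = (
        ",".join(map(str, sorted(state.available)))
        + "|"
        + ",".join(map(str, sorted(state.reserved)))
    ).encode()
    return (base_seed * 1_000_003 + zlib.crc32(key)) % (2**31 - 1)


class DynamicMinSet:
    """Re-solve + order + purchase-prefix policy.

    The annealer's seed is derived deterministically from the base seed and
    the state, so the policy is a stationary deterministic function of the
    state (a requirement of exact evaluation) and rollouts are reproducible.
    """

    def __init__(
        self,
        sa_params: SAParams | None = None,
        criterion: str = "utilitarian",
        m_B: float | None = None,
    ):
        self.sa_params = sa_params or SAParams()
        self.criterion = criterion
        self.m_B = m_B

    def __call__(self, state, budget, period, landscape):
        params = SAParams(
            iterations=self.sa_params.iterations,
            initial_temperature=self.sa_params.initial_temperature,
            cooling=self.sa_params.cooling,
            restarts=self.sa_params.restarts,
            seed=_state_seed(self.sa_params.seed, state),
        )
        return dynamic_minset_step(
            state, budget, landscape, params, self.criterion, self.m_B
        )


POLICY_NAMES = (
    "cheapest",
    "greedy-rich",
    "greedy-rar",
    "aug-rich",
    "aug-rar",
    "dyn-minset",
)


def make_policy(
    name: str,
    weights: WeightVector | None = None,
    sa_params: SAParams | None = None,
    criterion: str = "utilitarian",
    m_B: float | None = None,
):
    """Instantiate a policy by its command-line name."""
    if name == "cheapest":
        return CheapestFirst()
    if name == "greedy-rich":
        return GreedyPolicy("richness")
    if name == "greedy-rar":
        return GreedyPolicy("rarity")
    if name == "aug-rich":
        if weights is None:
            raise ValueError("aug-rich requires a weight vector")
        return GreedyPolicy("richness", weights)
    if name == "aug-rar":
        if weights is None:
            raise ValueError("aug-rar requires a weight vector")
        return GreedyPolicy("rarity", weights)
    if name == "dyn-minset":
        return DynamicMinSet(sa_params, criterion, m_B)
    raise ValueError(f"unknown policy {name!r}; choose from {POLICY_NAMES}")
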