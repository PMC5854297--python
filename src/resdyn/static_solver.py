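"""Static minimum-set solver: simulated annealing on the one-shot objective.

The static problem scores a candidate network ``N`` by

    r(N) = -cost(N) - BLM * Boundary(N) - sum_j SPF_j * Penalty(j) - CostThreshold(N),

where ``Penalty(j)`` is an estimate of the extra minimal cost needed to reach
target ``j`` from ``N`` (0 when met) and the SPF factor (default 1e6) makes
any target-meeting network beat any non-meeting one.  The annealer proposes
single-site additions/removals with Metropolis acceptance and geometric
cooling; a brute-force enumerator provides the exact optimum on small
instances and serves as the test oracle.

Sites already reserved in earlier periods are passed as ``locked``: they are
fixed in the network and contribute abundance and boundary but no monetary
cost (sunk), which is how the dynamic re-solve accounts for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .landscape import Landscape

__all__ = [
    "SAParams",
    "shortfall_penalty",
    "static_objective",
    "anneal",
    "brute_force_optimum",
]

_THRESHOLD_PENALTY = 1e12
_BRUTE_FORCE_CAP = 20


@dataclass(frozen=True)
class SAParams:
    """Annealing schedule.  ``initial_temperature=None`` sets it adaptively
    from the spread of 100 random-move objective deltas."""

    iterations: int = 20_000
    initial_temperature: float | None = None
    cooling: float = 0.999
    restarts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling must lie in (0, 1)")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def shortfall_penalty(
    landscape: Landscape,
    network: Iterable[int],
    j: int,
    pool: Iterable[int] | None = None,
) -> float:
    """Greedy estimate of the minimal extra cost to reach target ``j``.

    Unselected sites from ``pool`` (default: all sites) are added in order of
    cost per unit of habitat ``j`` until the target is met; the summed cost of
    the added sites is returned.  If the target is unattainable even with
    every remaining j-bearing site, their total cost plus ``alpha`` is
    returned.  0 when the target is already met.
    """
    net = set(landscape._check_network(network))
    target = float(landscape.targets[j - 1])
    have = landscape.abundance(net, j)
    if have >= target - 1e-12:
        return 0.0
    col = j - 1
    candidates = []
    universe = landscape.site_ids if pool is None else frozenset(pool)
    for sid in universe - net:
        h = landscape.site(sid).habitat[col]
        if h > 0:
            c = landscape.site(sid).cost
            candidates.append((c / h, sid, c, h))
    candidates.sort()
    added_cost = 0.0
    for _, _, c, h in candidates:
        added_cost += c
        have += h
        if have >= target - 1e-12:
            return added_cost
    return added_cost + landscape.alpha


def static_objective(
    landscape: Landscape,
    network: Iterable[int],
    locked: Iterable[int] = (),
    cost_threshold: float | None = None,
    pool: Iterable[int] | None = None,
) -> float:
    """The one-shot reward of ``network`` (higher is better).

    ``locked`` sites are sunk: they count for abundance and boundary but add
    no monetary cost.  The cost-threshold term is 0 when disabled (the
    default), else a large constant once the non-locked spend exceeds it.
    """
    net = frozenset(network)
    locked = frozenset(locked)
    if not locked <= net:
        raise ValueError("locked sites must be contained in the network")
    money = landscape.total_cost(net - locked)
    obj = -money - landscape.blm * landscape.boundary(net)
    for j in range(1, landscape.n_targets + 1):
        obj -= float(landscape.spf[j - 1]) * shortfall_penalty(landscape, net, j, pool)
    if cost_threshold is not None and money > cost_threshold + 1e-9:
        obj -= _THRESHOLD_PENALTY
    return obj


def brute_force_optimum(
    landscape: Landscape,
    available: Iterable[int],
    locked: Iterable[int] = (),
    cost_threshold: float | None = None,
) -> frozenset[int]:
    """Exhaustive maximization of the static objective (test oracle).

    Capped at 20 free sites.  Ties break toward the subset that appears first
    in ascending-id enumeration order.
    """
    free = sorted(set(available))
    locked = frozenset(locked)
    if len(free) > _BRUTE_FORCE_CAP:
        raise ValueError(f"brute force capped at {_BRUTE_FORCE_CAP} sites, got {len(free)}")
    pool = frozenset(free) | locked
    best_net, best_val = None, -math.inf
    for mask in range(1 << len(free)):
        net = locked | {free[i] for i in range(len(free)) if mask >> i & 1}
        val = static_objective(landscape, net, locked, cost_threshold, pool)
        if val > best_val + 1e-12:
            best_net, best_val = net, val
    return frozenset(best_net)


class _Evaluator:
    """Incremental objective bookkeeping for the annealer."""

    def __init__(
        self,
        landscape: Landscape,
        pool: frozenset[int],
        locked: frozenset[int],
        cost_threshold: float | None,
    ):
        self.ls = landscape
        self.locked = locked
        self.threshold = cost_threshold
        self.targets = landscape.targets
        self.spf = landscape.spf
        self.blm = landscape.blm
        ids = sorted(pool)
        self.free = [s for s in ids if s not in locked]
        # per-habitat fillers presorted by cost per unit habitat
        self.fillers: list[list[tuple[int, float, float]]] = []
        for col in range(landscape.n_targets):
            cand = [
                (sid, landscape.site(sid).cost, landscape.site(sid).habitat[col])
                for sid in ids
                if landscape.site(sid).habitat[col] > 0
            ]
            cand.sort(key=lambda t: t[1] / t[2])
            self.fillers.append(cand)
        self.selected: set[int] = set()
        self.abund = np.zeros(landscape.n_targets)
        self.money = 0.0
        self.bound = 0.0

    def reset(self, network: set[int]) -> None:
        self.selected = set()
        self.abund = np.zeros(self.ls.n_targets)
        self.money = 0.0
        self.bound = 0.0
        for sid in network:
            self.toggle(sid)

    def toggle(self, sid: int) -> None:
        site = self.ls.site(sid)
        sign = -1.0 if sid in self.selected else 1.0
        if sign > 0:
            self.selected.add(sid)
        else:
            self.selected.discard(sid)
        self.abund += sign * np.asarray(site.habitat[: self.ls.n_targets])
        if sid not in self.locked:
            self.money += sign * site.cost
        delta = site.perimeter
        for other, length in self.ls._adjacency[sid]:
            if other in self.selected and other != sid:
                delta -= 2.0 * length
        self.bound += sign * delta

    def violates_threshold(self) -> bool:
        return self.threshold is not None and self.money > self.threshold + 1e-9

    def objective(self) -> float:
        obj = -self.money - self.blm * self.bound
        for col in range(self.ls.n_targets):
            gap = self.targets[col] - self.abund[col]
            if gap > 1e-12:
                have = self.abund[col]
                cost = 0.0
                met = False
                for sid, c, h in self.fillers[col]:
                    if sid in self.selected:
                        continue
                    cost += c
                    have += h
                    if have >= self.targets[col] - 1e-12:
                        met = True
                        break
                if not met:
                    cost += self.ls.alpha
                obj -= float(self.spf[col]) * cost
        if self.violates_threshold():
            obj -= _THRESHOLD_PENALTY
        return obj


def anneal(
    landscape: Landscape,
    available: Iterable[int],
    locked: Iterable[int] = (),
    params: SAParams | None = None,
    cost_threshold: float | None = None,
) -> frozenset[int]:
    """Near-optimal static network by simulated annealing.

    Proposals toggle one random free site; acceptance is Metropolis on the
    objective delta with geometric cooling.  The best network seen across all
    restarts is returned (never one violating an enabled cost threshold).
    Deterministic for a given ``params.seed``.
    """
    params = params or SAParams()
    available = frozenset(available)
    locked = frozenset(locked)
    if not available:
        raise ValueError("available must be nonempty")
    pool = available | locked
    ev = _Evaluator(landscape, pool, locked, cost_threshold)
    free = ev.free
    if not free:
        return frozenset(locked)
    rng = np.random.default_rng(params.seed)

    ev.reset(set(locked))
    best_net = frozenset(locked)
    best_val = ev.objective() if not ev.violates_threshold() else -math.inf

    for _ in range(params.restarts):
        start = set(locked) | {s for s in free if rng.random() < 0.5}
        ev.reset(start)
        current = ev.objective()

        if params.initial_temperature is not None:
            temp = params.initial_temperature
        else:
            deltas = []
            for _ in range(100):
                sid = free[rng.integers(len(free))]
                ev.toggle(sid)
                deltas.append(ev.objective() - current)
                ev.toggle(sid)
            temp = max(float(np.std(deltas)), 1e-9)

        if current > best_val and not ev.violates_threshold():
            best_net, best_val = frozenset(ev.selected), current
        for _ in range(params.iterations):
            sid = free[rng.integers(len(free))]
            ev.toggle(sid)
            cand = ev.objective()
            delta = cand - current
            if delta >= 0 or rng.random() < math.exp(max(delta / temp, -700.0)):
                current = cand
                if current > best_val and not ev.violates_threshold():
                    best_net, best_val = frozenset(ev.selected), current
            else:
                ev.toggle(sid)
            temp *= params.cooling
    return best_net
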