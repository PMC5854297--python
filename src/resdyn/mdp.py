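"""Exact Markov-decision-process treatment of dynamic reserve design.

The state is the pair (available sites S, reserved network N̄); converted
sites are implied.  An action is a feasible purchase N ⊆ S with total cost
within the period budget B.  After purchasing, every remaining unreserved
site converts independently with its probability ``mu(s)``, giving the
product-form transition law over subsets of S \\ N.  Rewards are negative
purchase costs, plus — on the transition that empties S — the terminal
boundary and target-shortfall penalties; infeasible actions carry a large
negative sentinel standing in for −∞.  The optimal policy maximizes the
expected total (undiscounted) reward, and its value at the initial state is
the negative of the minimal expected extended cost (EEC).

Only small instances are tractable exactly (default cap: 12 sites); larger
problems are evaluated by Monte-Carlo simulation in :mod:`resdyn.evaluation`.

Two conventions worth noting:

* Once the current reserve meets every target, the process is frozen: the
  forced action is ∅ and the terminal cost accounting is applied immediately
  (further conversions cannot change the network).
* A state whose unreserved sites all have ``mu = 0`` never empties; waiting
  there is treated as absorbing with the terminal assessment of the current
  network, matching the simulation's horizon-cap semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .landscape import Landscape, ReserveState

__all__ = [
    "MDPInstance",
    "TabularPolicy",
    "ValueFunction",
    "transition_distribution",
    "transition_reward",
    "backward_induction",
    "exact_policy_value",
    "bellman_residual",
    "infeasible_sentinel",
]

_DEFAULT_CAP = 12


def infeasible_sentinel(landscape: Landscape) -> float:
    """Finite stand-in for the −∞ reward of prohibited actions."""
    return -1e6 * max(landscape.alpha, 1.0)


@dataclass(frozen=True)
class MDPInstance:
    """A landscape with a constant per-period budget ``B``."""

    landscape: Landscape
    budget: float

    def __post_init__(self) -> None:
        if self.budget <= 0:
            raise ValueError("budget must be > 0")

    def initial_state(self) -> ReserveState:
        ls = self.landscape
        return ReserveState(ls.site_ids - ls.initial_reserve, ls.initial_reserve)


class TabularPolicy(dict):
    """State → purchase-set mapping; usable under the policy contract."""

    def __call__(self, state, budget, period, landscape):
        try:
            return self[state]
        except KeyError:
            raise KeyError(
                f"state with |S|={len(state.available)}, |N̄|={len(state.reserved)} "
                "not covered by this tabular policy"
            ) from None


class ValueFunction(dict):
    """State → value (negative expected remaining extended cost)."""


def _is_feasible(state: ReserveState, action: frozenset, landscape: Landscape,
                 budget: float | None) -> bool:
    if not action <= state.available:
        return False
    if budget is not None and landscape.total_cost(action) > budget + 1e-9:
        return False
    return True


def transition_distribution(
    state: ReserveState,
    action: Iterable[int],
    landscape: Landscape,
    budget: float | None = None,
) -> dict[ReserveState, float]:
    """Successor distribution of one (state, action) pair.

    The support is every survivor subset S' ⊆ S \\ N with the purchase added
    to the reserve; each remaining site survives with probability 1 − mu(s),
    independently.  Empty-availability states self-loop, and so do infeasible
    actions (their prohibition is carried by the reward sentinel).
    """
    action = frozenset(action)
    if not state.available:
        return {state: 1.0}
    if not _is_feasible(state, action, landscape, budget):
        return {state: 1.0}
    rem = sorted(state.available - action)
    new_res = state.reserved | action
    out: dict[ReserveState, float] = {}
    for mask in range(1 << len(rem)):
        p = 1.0
        surv = []
        for i, sid in enumerate(rem):
            mu = landscape.site(sid).mu
            if mask >> i & 1:
                surv.append(sid)
                p *= 1.0 - mu
            else:
                p *= mu
        if p > 0.0:
            nxt = ReserveState(frozenset(surv), new_res)
            out[nxt] = out.get(nxt, 0.0) + p
    return out


def transition_reward(
    state: ReserveState,
    action: Iterable[int],
    next_state: ReserveState,
    landscape: Landscape,
    budget: float | None = None,
) -> float:
    """Reward of one transition: −purchase cost, plus the terminal
    boundary-and-penalty assessment exactly when availability empties."""
    action = frozenset(action)
    if not state.available:
        return 0.0 if not action else infeasible_sentinel(landscape)
    if not _is_feasible(state, action, landscape, budget):
        return infeasible_sentinel(landscape)
    r = -landscape.total_cost(action)
    if not next_state.available:
        final = state.reserved | action
        r -= landscape.blm * landscape.boundary(final) + landscape.penalty(final)
    return r


class _FastSolver:
    """Bitmask dynamic programming over (available, reserved) masks."""

    def __init__(self, instance: MDPInstance):
        ls = instance.landscape
        self.ls = ls
        self.B = float(instance.budget)
        self.ids = list(ls.ordered_ids)
        self.n = len(self.ids)
        self.cost = [ls.site(s).cost for s in self.ids]
        self.mu = [ls.site(s).mu for s in self.ids]
        self.hab = [list(ls.site(s).habitat[: ls.n_targets]) for s in self.ids]
        self.targets = [float(t) for t in ls.targets]
        self.J = ls.n_targets
        self.blm = ls.blm
        self.alpha = ls.alpha
        self._met: dict[int, bool] = {}
        self._bound: dict[int, float] = {}
        self._probs: dict[int, list[tuple[int, float]]] = {}
        self._actions: dict[int, list[int]] = {}
        self._v: dict[tuple[int, int], float] = {}
        self._a: dict[tuple[int, int], int] = {}

    # -- mask helpers -------------------------------------------------------

    def mask_of(self, sites: Iterable[int]) -> int:
        m = 0
        for sid in sites:
            m |= 1 << self.ls.index_of(sid)
        return m

    def set_of(self, mask: int) -> frozenset[int]:
        return frozenset(self.ids[i] for i in range(self.n) if mask >> i & 1)

    def targets_met(self, res_mask: int) -> bool:
        cached = self._met.get(res_mask)
        if cached is not None:
            return cached
        sums = [0.0] * self.J
        m = res_mask
        while m:
            i = (m & -m).bit_length() - 1
            hi = self.hab[i]
            for j in range(self.J):
                sums[j] += hi[j]
            m &= m - 1
        met = all(sums[j] >= self.targets[j] - 1e-12 for j in range(self.J))
        self._met[res_mask] = met
        return met

    def boundary(self, res_mask: int) -> float:
        cached = self._bound.get(res_mask)
        if cached is not None:
            return cached
        b = self.ls.boundary(self.set_of(res_mask))
        self._bound[res_mask] = b
        return b

    def terminal_value(self, res_mask: int) -> float:
        pen = 0.0 if self.targets_met(res_mask) else self.alpha
        return -(self.blm * self.boundary(res_mask) + pen)

    def survivor_probs(self, rem_mask: int) -> list[tuple[int, float]]:
        """All (survivor-mask, probability) pairs for the sites in rem_mask."""
        cached = self._probs.get(rem_mask)
        if cached is not None:
            return cached
        if rem_mask == 0:
            out = [(0, 1.0)]
        else:
            low = rem_mask & -rem_mask
            i = low.bit_length() - 1
            rest = self.survivor_probs(rem_mask ^ low)
            mu = self.mu[i]
            out = []
            for m, p in rest:
                if mu < 1.0:
                    out.append((m | low, p * (1.0 - mu)))
                if mu > 0.0:
                    out.append((m, p * mu))
        self._probs[rem_mask] = out
        return out

    def feasible_actions(self, avail_mask: int) -> list[int]:
        """Purchase masks within budget (∅ included), in lexicographic set order."""
        cached = self._actions.get(avail_mask)
        if cached is not None:
            return cached
        idxs = [i for i in range(self.n) if avail_mask >> i & 1]
        found: list[int] = []

        def dfs(pos: int, mask: int, budget: float) -> None:
            found.append(mask)
            for k in range(pos, len(idxs)):
                c = self.cost[idxs[k]]
                if c <= budget + 1e-9:
                    dfs(k + 1, mask | (1 << idxs[k]), budget - c)

        dfs(0, 0, self.B)
        found.sort(key=lambda m: tuple(i for i in range(self.n) if m >> i & 1))
        self._actions[avail_mask] = found
        return found

    def _mask_cost(self, mask: int) -> float:
        c = 0.0
        while mask:
            i = (mask & -mask).bit_length() - 1
            c += self.cost[i]
            mask &= mask - 1
        return c

    # -- optimal values -----------------------------------------------------

    def action_value(self, avail: int, res: int, act: int) -> float:
        """Q(x, a) with the ∅-action self-loop resolved analytically."""
        rem = avail & ~act
        new_res = res | act
        q = -self._mask_cost(act)
        if act == 0:
            rest = 0.0
            p_stay = 0.0
            for surv, p in self.survivor_probs(rem):
                if surv == rem:
                    p_stay = p
                else:
                    rest += p * self.value(surv, new_res)
            if p_stay >= 1.0 - 1e-15:
                # nothing can ever convert: waiting is absorbing
                return self.terminal_value(new_res)
            return (q + rest) / (1.0 - p_stay)
        for surv, p in self.survivor_probs(rem):
            q += p * self.value(surv, new_res)
        return q

    def value(self, avail: int, res: int) -> float:
        if self.targets_met(res):
            return -self.blm * self.boundary(res)
        if avail == 0:
            return self.terminal_value(res)
        key = (avail, res)
        cached = self._v.get(key)
        if cached is not None:
            return cached
        best, best_act = -math.inf, 0
        for act in self.feasible_actions(avail):
            q = self.action_value(avail, res, act)
            if q > best + 1e-12:
                best, best_act = q, act
        self._v[key] = best
        self._a[key] = best_act
        return best

    # -- fixed-policy values ------------------------------------------------

    def policy_value(self, policy, memo: dict) -> float:
        ls = self.ls

        def ev(avail: int, res: int) -> float:
            """Expected remaining extended cost (positive) from a state."""
            if self.targets_met(res):
                return self.blm * self.boundary(res)
            if avail == 0:
                return -self.terminal_value(res)
            key = (avail, res)
            if key in memo:
                return memo[key]
            state = ReserveState(self.set_of(avail), self.set_of(res))
            act_set = frozenset(policy(state, self.B, 0, ls))
            if not act_set <= state.available:
                raise ValueError("policy returned unavailable sites")
            act = self.mask_of(act_set)
            if self._mask_cost(act) > self.B + 1e-9:
                raise ValueError("policy returned an unaffordable purchase")
            rem = avail & ~act
            new_res = res | act
            cost = self._mask_cost(act)
            if act == 0:
                rest, p_stay = 0.0, 0.0
                for surv, p in self.survivor_probs(rem):
                    if surv == rem:
                        p_stay = p
                    else:
                        rest += p * ev(surv, new_res)
                val = (
                    -self.terminal_value(new_res)
                    if p_stay >= 1.0 - 1e-15
                    else (cost + rest) / (1.0 - p_stay)
                )
            else:
                val = cost
                for surv, p in self.survivor_probs(rem):
                    val += p * ev(surv, new_res)
            memo[key] = val
            return val

        init = self.mask_of(ls.site_ids - ls.initial_reserve), self.mask_of(
            ls.initial_reserve
        )
        return ev(*init)


def _check_cap(instance: MDPInstance, cap: int) -> None:
    n = instance.landscape.n_sites
    if n > cap:
        raise ValueError(
            f"exact solution capped at {cap} sites (instance has {n}); "
            "use Monte-Carlo evaluation (resdyn.evaluation.estimate_eec) instead"
        )


def backward_induction(
    instance: MDPInstance, cap: int = _DEFAULT_CAP
) -> tuple[TabularPolicy, ValueFunction]:
    """Optimal policy and value function by dynamic programming.

    States are expanded from the initial state and solved by memoized Bellman
    recursion (successor availability sets are always strictly smaller except
    for the analytically resolved wait self-loop, so the recursion is the
    backward sweep in disguise).  Ties between equally good purchases break
    toward the lexicographically smallest site set.  The value at the initial
    state equals minus the optimal expected extended cost.
    """
    _check_cap(instance, cap)
    import sys

    solver = _FastSolver(instance)
    ls = instance.landscape
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10_000))
    try:
        solver.value(
            solver.mask_of(ls.site_ids - ls.initial_reserve),
            solver.mask_of(ls.initial_reserve),
        )
    finally:
        sys.setrecursionlimit(old_limit)
    policy = TabularPolicy()
    values = ValueFunction()
    for (avail, res), v in solver._v.items():
        state = ReserveState(solver.set_of(avail), solver.set_of(res))
        values[state] = v
        policy[state] = solver.set_of(solver._a[(avail, res)])
    return policy, values


def optimal_eec(instance: MDPInstance, cap: int = _DEFAULT_CAP) -> float:
    """Expected extended cost of the optimal policy (convenience wrapper)."""
    _check_cap(instance, cap)
    solver = _FastSolver(instance)
    ls = instance.landscape
    v0 = solver.value(
        solver.mask_of(ls.site_ids - ls.initial_reserve),
        solver.mask_of(ls.initial_reserve),
    )
    return -v0


def exact_policy_value(policy, instance: MDPInstance, cap: int = _DEFAULT_CAP) -> float:
    """Exact expected extended cost of a deterministic stationary policy.

    Recurses over the transition tree with memoization on (S, N̄); the policy
    is queried with the constant budget and period 0 (the exact model carries
    no budget carryover in its state).
    """
    _check_cap(instance, cap)
    solver = _FastSolver(instance)
    return solver.policy_value(policy, {})


def target_reachable(
    landscape: Landscape,
    state: ReserveState,
    budget: float,
) -> bool:
    """Whether any continuation can still meet every target from ``state``.

    Exhaustive search over feasible purchase sequences under the best-case
    conversion outcome (no further losses): if no purchase order reaches the
    targets even then, no continuation policy can.  Budgets are per period
    with no carryover, matching the exact model.
    """
    solver = _FastSolver(MDPInstance(landscape, budget))
    memo: dict[tuple[int, int], bool] = {}

    def reach(avail: int, res: int) -> bool:
        if solver.targets_met(res):
            return True
        if avail == 0:
            return False
        key = (avail, res)
        if key in memo:
            return memo[key]
        memo[key] = False  # guard against revisiting while expanding
        ok = any(
            reach(avail & ~act, res | act)
            for act in solver.feasible_actions(avail)
            if act != 0
        )
        memo[key] = ok
        return ok

    return reach(solver.mask_of(state.available), solver.mask_of(state.reserved))


def bellman_residual(
    instance: MDPInstance,
    values: Mapping[ReserveState, float],
) -> float:
    """Max |V(x) − max_a Σ P(x'|x,a)(r + V(x'))| over the stored states.

    Terminal and target-frozen states are assessed directly and skipped.
    A residual at floating tolerance certifies the fixed point.
    """
    ls = instance.landscape
    solver = _FastSolver(instance)
    worst = 0.0
    for state, v in values.items():
        if not state.available or solver.targets_met(solver.mask_of(state.reserved)):
            continue
        avail = solver.mask_of(state.available)
        res = solver.mask_of(state.reserved)
        best = -math.inf
        for act in solver.feasible_actions(avail):
            best = max(best, solver.action_value(avail, res, act))
        worst = max(worst, abs(v - best))
    return worst
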