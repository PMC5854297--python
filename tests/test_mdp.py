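"""Exact MDP semantics: transitions, rewards, backward induction."""

import math

import numpy as np
import pytest

from resdyn.landscape import Landscape, ReserveState, Site
from resdyn.mdp import (
    MDPInstance,
    backward_induction,
    bellman_residual,
    exact_policy_value,
    infeasible_sentinel,
    optimal_eec,
    target_reachable,
    transition_distribution,
    transition_reward,
)
from resdyn.policies import GreedyPolicy

from conftest import random_landscape


def naive_optimal(landscape, budget):
    """Independent brute-force expectimax oracle (sets, no masks, no caching
    of action lists) returning (value, best first action) at the start state."""
    ids = frozenset(landscape.site_ids)

    from functools import lru_cache
    from itertools import chain, combinations

    def subsets(s):
        s = sorted(s)
        return chain.from_iterable(combinations(s, k) for k in range(len(s) + 1))

    @lru_cache(maxsize=None)
    def value(avail, res):
        if landscape.targets_met(res):
            return -landscape.blm * landscape.boundary(res)
        if not avail:
            return -(landscape.blm * landscape.boundary(res) + landscape.penalty(res))
        best = -math.inf
        for act in subsets(avail):
            act = frozenset(act)
            if landscape.total_cost(act) > budget + 1e-9:
                continue
            rem = sorted(avail - act)
            q, p_stay, rest = -landscape.total_cost(act), 0.0, 0.0
            for mask in range(1 << len(rem)):
                surv = frozenset(rem[i] for i in range(len(rem)) if mask >> i & 1)
                p = 1.0
                for sid in rem:
                    mu = landscape.site(sid).mu
                    p *= (1 - mu) if sid in surv else mu
                if act or surv != frozenset(rem):
                    rest += p * value(surv, res | act)
                else:
                    p_stay = p
            if not act:
                q = (
                    value(frozenset(), res)
                    if p_stay >= 1 - 1e-15
                    else rest / (1 - p_stay)
                )
            else:
                q += rest
            best = max(best, q)
        return best

    start = ids - landscape.initial_reserve
    v = value(start, landscape.initial_reserve)
    best_act, best_q = None, -math.inf
    for act in subsets(start):
        act = frozenset(act)
        if act and landscape.total_cost(act) <= budget + 1e-9:
            rem = sorted(start - act)
            q = -landscape.total_cost(act)
            for mask in range(1 << len(rem)):
                surv = frozenset(rem[i] for i in range(len(rem)) if mask >> i & 1)
                p = 1.0
                for sid in rem:
                    mu = landscape.site(sid).mu
                    p *= (1 - mu) if sid in surv else mu
                q += p * value(surv, landscape.initial_reserve | act)
            if q > best_q + 1e-12:
                best_act, best_q = act, q
    return v, best_act


def test_transition_support_and_probabilities(worked3):
    state = ReserveState(frozenset({1, 2, 3}), frozenset())
    dist = transition_distribution(state, {1}, worked3, budget=1.0)
    assert len(dist) == 4  # all subsets of the two remaining sites
    assert sum(dist.values()) == pytest.approx(1.0)
    assert all(s.reserved == {1} for s in dist)
    # two remaining sites at mu = 0.5: each outcome has probability 1/4
    assert all(p == pytest.approx(0.25) for p in dist.values())


def test_transition_with_no_conversion_risk_is_deterministic():
    sites = [Site(i, 1.0, (1.0,), 0.0, 4.0) for i in (1, 2, 3)]
    ls = Landscape(sites, targets=(2.0,))
    state = ReserveState(frozenset({1, 2, 3}), frozenset())
    dist = transition_distribution(state, {1}, ls, budget=1.0)
    assert dist == {ReserveState(frozenset({2, 3}), frozenset({1})): 1.0}


def test_infeasible_action_self_loops_with_sentinel(worked4):
    state = ReserveState(frozenset({1, 2}), frozenset({3}))
    dist = transition_distribution(state, {1, 2}, worked4, budget=1.0)  # too costly
    assert dist == {state: 1.0}
    r = transition_reward(state, {1, 2}, state, worked4, budget=1.0)
    assert r == infeasible_sentinel(worked4) < -1e6


def test_reward_cases(worked4):
    full = ReserveState(frozenset({1, 2, 3, 4}), frozenset())
    nxt = ReserveState(frozenset({2, 4}), frozenset({1}))
    assert transition_reward(full, {1}, nxt, worked4, budget=1.0) == -1.0
    empty = ReserveState(frozenset(), frozenset({3}))
    assert transition_reward(empty, set(), empty, worked4) == 0.0
    # terminal transition, targets unmet, BLM=0: purchase cost plus alpha
    terminal = ReserveState(frozenset(), frozenset({3, 4}))
    mid = ReserveState(frozenset({4}), frozenset({3}))
    r = transition_reward(mid, {4}, terminal, worked4, budget=1.0)
    assert r == pytest.approx(-1.0)  # {3,4} meets the target: no penalty
    unmet = ReserveState(frozenset(), frozenset({2}))
    r = transition_reward(
        ReserveState(frozenset({2}), frozenset()), {2}, unmet, worked4, budget=1.0
    )
    assert r == pytest.approx(-1.0 - worked4.alpha)


def test_transition_probabilities_normalize_on_random_instances():
    rng = np.random.default_rng(8)
    for seed in range(5):
        ls = random_landscape(seed, n=5)
        ids = sorted(ls.site_ids)
        avail = frozenset(s for s in ids if rng.random() < 0.7)
        res = frozenset(set(ids) - avail)
        state = ReserveState(avail, res)
        for sid in sorted(avail):
            dist = transition_distribution(state, {sid}, ls, budget=10.0)
            assert sum(dist.values()) == pytest.approx(1.0)


def test_single_covering_site_is_bought_immediately():
    sites = [Site(1, 0.8, (9.0,), 0.4, 4.0), Site(2, 1.0, (1.0,), 0.4, 4.0)]
    ls = Landscape(sites, targets=(8.0,))
    policy, values = backward_induction(MDPInstance(ls, 1.0))
    init = ReserveState(frozenset({1, 2}), frozenset())
    assert policy[init] == {1}
    assert -values[init] == pytest.approx(0.8)


def test_backward_induction_matches_brute_force_oracle(worked4, worked3):
    for ls in (worked4, worked3):
        inst = MDPInstance(ls, 1.0)
        v_oracle, act_oracle = naive_optimal(ls, 1.0)
        policy, values = backward_induction(inst)
        init = inst.initial_state()
        assert values[init] == pytest.approx(v_oracle, abs=1e-9)
        assert policy[init] == act_oracle
    # the safest opening in the 4-site example protects the largest amount
    inst4 = MDPInstance(worked4, 1.0)
    policy4, _ = backward_induction(inst4)
    assert policy4[inst4.initial_state()] == {1}


def test_bellman_residual_vanishes():
    for seed in (0, 1):
        ls = random_landscape(seed, n=5, blm=0.5 if seed else 0.0)
        inst = MDPInstance(ls, 1.5)
        _, values = backward_induction(inst)
        assert bellman_residual(inst, values) < 1e-9


def test_never_buy_policy_costs_alpha(worked4):
    never = lambda state, budget, period, ls: frozenset()
    assert exact_policy_value(never, MDPInstance(worked4, 1.0)) == pytest.approx(
        worked4.alpha
    )


def test_greedy_without_risk_executes_the_plan():
    sites = [
        Site(i + 1, 1.0, (h,), 0.0, 4.0) for i, h in enumerate((6.0, 2.0, 4.0, 3.0))
    ]
    ls = Landscape(sites, targets=(7.0,))
    v = exact_policy_value(GreedyPolicy("richness"), MDPInstance(ls, 1.0))
    assert v == pytest.approx(2.0)  # buys s1 then s3, deterministically


def test_optimal_dominates_any_policy(worked4):
    inst = MDPInstance(worked4, 1.0)
    opt = optimal_eec(inst)
    for policy in (GreedyPolicy("richness"), GreedyPolicy("rarity")):
        assert opt <= exact_policy_value(policy, inst) + 1e-9


def test_optimal_eec_monotone_in_budget_and_risk():
    for seed in range(4):
        rng = np.random.default_rng(seed)
        hab = rng.uniform(0, 10, (5, 2))
        mu = rng.uniform(0.05, 0.5, 5)
        costs = rng.uniform(0.5, 2.0, 5)

        def make(muv):
            sites = [
                Site(i + 1, float(costs[i]), tuple(hab[i]), float(muv[i]), 4.0)
                for i in range(5)
            ]
            return Landscape(sites, targets=0.5 * hab.sum(axis=0))

        base = optimal_eec(MDPInstance(make(mu), 1.0))
        assert optimal_eec(MDPInstance(make(mu), 2.0)) <= base + 1e-9
        riskier = np.minimum(1.0, mu + 0.15)
        assert optimal_eec(MDPInstance(make(riskier), 1.0)) >= base - 1e-9


def test_exact_solver_cap():
    rng = np.random.default_rng(0)
    hab = rng.uniform(0, 10, (13, 1))
    sites = [Site(i + 1, 1.0, tuple(hab[i]), 0.2, 4.0) for i in range(13)]
    ls = Landscape(sites, targets=(5.0,))
    with pytest.raises(ValueError, match="Monte-Carlo"):
        backward_induction(MDPInstance(ls, 1.0))


def test_target_reachability_enumeration(worked4):
    # all three remaining sites lost after reserving s1: only then unreachable
    assert target_reachable(
        worked4, ReserveState(frozenset({2, 4}), frozenset({1})), 1.0
    )
    assert not target_reachable(worked4, ReserveState(frozenset(), frozenset({1})), 1.0)
    assert not target_reachable(
        worked4, ReserveState(frozenset({2}), frozenset({3})), 1.0
    )
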