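"""Decision rules: scores, greedy purchasing, dynamic minimum-set policy."""

import numpy as np
import pytest

from resdyn.evaluation import BudgetModel, rollout, sample_scenario
from resdyn.landscape import Landscape, ReserveState, Site
from resdyn.policies import (
    CheapestFirst,
    DynamicMinSet,
    GreedyPolicy,
    WeightVector,
    cheapest_first_step,
    dynamic_minset_step,
    greedy_step,
    make_policy,
    rarity_score,
    richness_score,
)
from resdyn.static_solver import SAParams

from conftest import random_landscape


@pytest.fixture
def full_state(worked4):
    return ReserveState(frozenset(worked4.site_ids), frozenset())


def test_richness_scores_match_hand_calculation(worked4, full_state):
    scores = [richness_score(s, full_state, worked4) for s in (1, 2, 3, 4)]
    assert scores == pytest.approx([6 / 7, 2 / 7, 4 / 7, 3 / 7])
    assert int(np.argmax(scores)) == 0  # site s1 first


def test_rarity_scores_match_hand_calculation(worked4, full_state):
    scores = [rarity_score(s, full_state, worked4) for s in (1, 2, 3, 4)]
    assert scores == pytest.approx([6 / 15, 2 / 15, 4 / 15, 3 / 15])


def test_met_target_is_rank_neutral_for_richness():
    sites = [
        Site(1, 1.0, (5.0, 1.0), 0.1, 4.0),
        Site(2, 1.0, (1.0, 5.0), 0.1, 4.0),
        Site(3, 1.0, (9.0, 2.0), 0.1, 4.0),
    ]
    ls = Landscape(sites, targets=(4.0, 4.0))
    state = ReserveState(frozenset({1, 2}), frozenset({3}))  # habitat 1 already met
    s1 = richness_score(1, state, ls)
    s2 = richness_score(2, state, ls)
    # met habitat contributes the constant 1 to both; ranking driven by h2 only
    assert s2 > s1
    assert s1 == pytest.approx(1.0 + (1.0 / 4.0) / 1.0)


def test_scores_invariant_to_uniform_weight_rescaling(worked4, full_state):
    w = WeightVector((1.3,), lambda_c=0.7)
    w2 = WeightVector((2.6,), lambda_c=1.4)
    for s in (1, 2, 3, 4):
        assert richness_score(s, full_state, worked4, w) == pytest.approx(
            richness_score(s, full_state, worked4, w2)
        )
        assert rarity_score(s, full_state, worked4, w) == pytest.approx(
            rarity_score(s, full_state, worked4, w2)
        )


def test_weight_vector_validation():
    with pytest.raises(ValueError):
        WeightVector((1.0, -1.0))
    with pytest.raises(ValueError):
        WeightVector((1.0,), lambda_c=0.0)


def test_greedy_step_iterates_until_budget_spent(worked4, full_state):
    assert greedy_step(full_state, 2.0, worked4, "richness") == {1, 3}
    assert greedy_step(full_state, 1.0, worked4, "richness") == {1}
    assert greedy_step(full_state, 0.5, worked4, "richness") == frozenset()


def test_greedy_step_stops_when_targets_met():
    sites = [Site(1, 1.0, (9.0,), 0.1, 4.0), Site(2, 1.0, (9.0,), 0.1, 4.0)]
    ls = Landscape(sites, targets=(8.0,))
    state = ReserveState(frozenset({1, 2}), frozenset())
    assert greedy_step(state, 5.0, ls, "rarity") == {1}


def test_richness_and_rarity_agree_for_single_habitat_equal_costs(worked4, full_state):
    rich = [richness_score(s, full_state, worked4) for s in (1, 2, 3, 4)]
    rar = [rarity_score(s, full_state, worked4) for s in (1, 2, 3, 4)]
    assert np.argsort(rich).tolist() == np.argsort(rar).tolist()


def test_cheapest_first():
    sites = [
        Site(1, 5.0, (1.0,), 0.1, 4.0),
        Site(2, 1.0, (1.0,), 0.1, 4.0),
        Site(3, 3.0, (1.0,), 0.1, 4.0),
    ]
    ls = Landscape(sites, targets=(3.0,))
    state = ReserveState(frozenset({1, 2, 3}), frozenset())
    assert cheapest_first_step(state, 4.0, ls) == {2, 3}
    assert cheapest_first_step(state, 0.0, ls) == frozenset()


def test_cheapest_first_tie_breaks_by_id(worked4, full_state):
    assert cheapest_first_step(full_state, 2.0, worked4) == {1, 2}


def test_dynamic_minset_buys_whole_solution_when_affordable(worked4, full_state):
    buy = dynamic_minset_step(
        full_state, 10.0, worked4, SAParams(iterations=2000, seed=0)
    )
    assert worked4.targets_met(buy)
    assert worked4.total_cost(buy) == 2.0


def test_dynamic_minset_prefix_prefers_the_safer_large_site(worked4, full_state):
    # any cost-2 static solution containing s1 is ordered s1-first for common mu
    buy = dynamic_minset_step(
        full_state, 1.0, worked4, SAParams(iterations=2000, seed=0)
    )
    assert len(buy) == 1
    assert buy <= {1, 3, 4}  # first element of an ordered minimum-cost solution


def test_dynamic_minset_without_risk_spends_the_static_optimum():
    ls = random_landscape(21, n=7)
    riskless = Landscape(
        [Site(s.id, s.cost, s.habitat, 0.0, s.perimeter) for s in ls.sites],
        ls.boundaries,
        ls.targets,
    )
    policy = DynamicMinSet(SAParams(iterations=3000, seed=2), m_B=1.0)
    scenario = sample_scenario(riskless, BudgetModel.constant(1.0), seed=0, horizon_cap=60)
    result = rollout(policy, scenario, riskless)
    from resdyn.static_solver import brute_force_optimum

    optimum = brute_force_optimum(riskless, riskless.site_ids)
    assert result.targets_met
    assert result.spent == pytest.approx(riskless.total_cost(optimum))


@pytest.mark.parametrize(
    "name", ["cheapest", "greedy-rich", "greedy-rar", "dyn-minset"]
)
def test_policy_contract_fuzz(name):
    policy = make_policy(
        name, sa_params=SAParams(iterations=300, restarts=1, seed=0), m_B=1.0
    )
    rng = np.random.default_rng(3)
    for seed in range(6):
        ls = random_landscape(seed + 30, n=7)
        ids = sorted(ls.site_ids)
        avail = frozenset(s for s in ids if rng.random() < 0.8)
        reserved = frozenset(
            s for s in set(ids) - avail if rng.random() < 0.5
        )
        state = ReserveState(avail, reserved)
        budget = float(rng.uniform(0.0, 4.0))
        buy = policy(state, budget, 1, ls)
        assert buy <= avail
        assert ls.total_cost(buy) <= budget + 1e-9


def test_augmented_policy_requires_weights():
    with pytest.raises(ValueError):
        make_policy("aug-rar")
    policy = make_policy("aug-rar", weights=WeightVector((2.0, 0.5)))
    assert isinstance(policy, GreedyPolicy)


def test_all_policies_halt_on_rollout():
    ls = random_landscape(55, n=8)
    bm = BudgetModel.constant(1.0)
    for name in ("cheapest", "greedy-rich", "greedy-rar"):
        policy = make_policy(name)
        scenario = sample_scenario(ls, bm, seed=9, horizon_cap=300)
        result = rollout(policy, scenario, ls)
        assert result.targets_met or result.periods <= 300
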