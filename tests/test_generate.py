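"""Synthetic landscape generators: fields, geometry, threat and cost models."""

import math

import numpy as np
import pytest

from resdyn.evaluation import BudgetModel
from resdyn.generate import (
    BenchmarkSpec,
    GRFSpec,
    assign_conversion_rates,
    assign_costs,
    build_benchmark,
    fixture_worked_examples,
    grid_geometry,
    normalize_to_area,
    simulate_grf_habitats,
    voronoi_landscape,
)


def test_degenerate_field_returns_the_mean():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    hab = simulate_grf_habitats(pts, [GRFSpec(mean=5.0, sill=1e-12, range_=2.0)], seed=0)
    assert np.allclose(hab, 5.0, atol=1e-4)


def test_field_correlation_follows_exponential_kernel():
    d, rng_param = 1.5, 2.0
    pts = np.array([[0.0, 0.0], [d, 0.0]])
    spec = GRFSpec(mean=0.0, sill=1.0, range_=rng_param)
    draws = np.array(
        [
            # large mean shift avoids the zero-truncation distorting the correlation
            simulate_grf_habitats(pts, [GRFSpec(100.0, 1.0, rng_param)], seed=s)[:, 0]
            for s in range(3000)
        ]
    )
    corr = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
    assert corr == pytest.approx(math.exp(-d / rng_param), abs=0.06)


def test_normalized_scale_field_parameters_accepted():
    # five-habitat benchmark convention: sill ~1 with a separate variance
    spec = GRFSpec(mean=51582.0, sill=0.954, range_=0.888, variance=153047.0)
    pts = np.array([[0.2, 0.2], [0.8, 0.7]])
    draws = np.array(
        [simulate_grf_habitats(pts, [spec], seed=s)[0, 0] for s in range(2000)]
    )
    assert draws.std() == pytest.approx(math.sqrt(153047.0), rel=0.1)
    with pytest.raises(ValueError):
        GRFSpec(mean=1.0, sill=0.0, range_=1.0)


def test_voronoi_single_site_is_the_extent():
    geom = voronoi_landscape(1, (3.0, 2.0), seed=0)
    assert geom.perimeters[0] == pytest.approx(10.0)
    assert geom.areas[0] == pytest.approx(6.0)


@pytest.mark.parametrize("seed", [0, 1])
def test_voronoi_union_identities(seed):
    geom = voronoi_landscape(50, (4.0, 5.0), seed=seed)
    assert geom.areas.sum() == pytest.approx(20.0, rel=1e-9)
    full = geom.perimeters.sum() - 2 * sum(geom.shared.values())
    assert full == pytest.approx(2 * (4.0 + 5.0), rel=1e-9)


def test_grid_geometry_combinatorics():
    geom = grid_geometry(3, 3)
    assert geom.n == 9
    assert np.all(geom.perimeters == 4.0)
    assert len(geom.shared) == 12  # interior shared edges of a 3x3 grid
    assert all(v == 1.0 for v in geom.shared.values())


def test_noncorrelated_rates_stay_in_stated_interval():
    hab = np.random.default_rng(0).uniform(0, 10, (200, 3))
    mu = assign_conversion_rates(hab, "noncorrelated", seed=1)
    assert np.all((mu >= 0.01) & (mu <= 0.3))


def test_correlated_rates_split_by_first_habitat_share():
    hab = np.zeros((100, 3))
    hab[:50, 0] = 5.0  # h1 is half the site's habitat
    hab[:50, 1] = 5.0
    hab[50:, 1] = 10.0  # no h1 at all
    mu = assign_conversion_rates(hab, "correlated", seed=2)
    assert np.all((mu[:50] >= 0.02) & (mu[:50] <= 0.6))
    assert np.all((mu[50:] >= 0.001) & (mu[50:] <= 0.1))


def test_category_rates_use_cumulative_target_share_of_area():
    hab = np.array([[1.0, 1.0, 8.0], [2.5, 2.0, 5.5], [4.0, 4.0, 2.0]] * 40)
    areas = np.full(120, 10.0)
    mu = assign_conversion_rates(hab, "category", seed=3, n_targets=2, areas=areas)
    assert np.all((mu[0::3] >= 0.001) & (mu[0::3] <= 0.1))  # 20% target share
    assert np.all((mu[1::3] >= 0.01) & (mu[1::3] <= 0.3))  # 45%
    assert np.all((mu[2::3] >= 0.02) & (mu[2::3] <= 0.6))  # 80%
    with pytest.raises(ValueError):
        assign_conversion_rates(hab, "category", seed=3)
    with pytest.raises(ValueError):
        assign_conversion_rates(hab, "nope", seed=3)


def test_cost_models():
    hab = np.random.default_rng(4).uniform(0, 5, (10_000, 2))
    assert np.all(assign_costs(hab, "unit", 0) == 1.0)
    linked = assign_costs(np.array([[4.0, 6.0]]), "habitat_linked", 0)
    assert linked[0] == pytest.approx(40_000.0)
    areas = np.random.default_rng(5).uniform(0.5, 2.0, 10_000)
    costs = assign_costs(hab, "exponential_area", seed=6, areas_km2=areas)
    assert (costs / areas).mean() == pytest.approx(25_242.0, rel=0.05)


def test_normalize_to_area_rescales_proportionally():
    hab = np.array([[6.0, 6.0], [1.0, 1.0]])
    out = normalize_to_area(hab, np.array([4.0, 4.0]))
    assert np.allclose(out[0], [2.0, 2.0])
    assert np.allclose(out[1], [1.0, 1.0])


def test_worked_example_fixtures(worked4, worked3):
    assert worked4.targets_met({3, 4})
    assert worked4.extended_cost({1, 3}) == worked4.extended_cost({3, 4}) == 2.0
    ids = sorted(worked3.site_ids)
    for a in ids:
        assert not worked3.targets_met({a})
        for b in ids:
            if a < b:
                assert worked3.targets_met({a, b})


def test_small9_benchmark_matches_stated_setup():
    ls, budget = build_benchmark(BenchmarkSpec("small9", seed=3))
    assert ls.n_sites == 9
    assert np.all(ls.cost_array == 1.0)
    assert ls.n_targets == 2
    assert np.allclose(ls.targets, 0.5 * ls.habitat_matrix[:, :2].sum(axis=0))
    assert ls.habitat_matrix.shape[1] == 3  # third habitat is non-target filler
    assert budget == BudgetModel.constant(1.0)
    assert np.all((ls.mu_array >= 0.01) & (ls.mu_array <= 0.3))


def test_large880_benchmark_matches_stated_setup():
    ls, budget = build_benchmark(BenchmarkSpec("large880", seed=1))
    assert ls.n_sites == 880
    assert set(budget.amounts) == {5e6, 3e6, 1e6}
    assert budget.mean() == pytest.approx(5e6 * 2 / 3 + 3e6 / 6 + 1e6 / 6)
    h12 = ls.habitat_matrix[:, 0] + ls.habitat_matrix[:, 1]
    assert np.allclose(ls.cost_array, 4000.0 * h12)


def test_ehnwr_benchmark_targets_and_normalization():
    ls, budget = build_benchmark(BenchmarkSpec("ehnwr", seed=2, n_sites=40))
    assert ls.n_targets == 5
    totals = ls.habitat_matrix[:, :5].sum(axis=0)
    assert np.allclose(ls.targets / totals, (0.67, 0.388, 0.26, 0.32, 0.388))
    areas = ls.geometry.areas
    assert np.all(ls.habitat_matrix.sum(axis=1) <= areas * (1 + 1e-9))
    assert not budget.is_constant


def test_same_seed_reproduces_identical_instances():
    a, _ = build_benchmark(BenchmarkSpec("small9", seed=11, conversion_mode="correlated"))
    b, _ = build_benchmark(BenchmarkSpec("small9", seed=11, conversion_mode="correlated"))
    c, _ = build_benchmark(BenchmarkSpec("small9", seed=12, conversion_mode="correlated"))
    assert a == b
    assert a != c
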