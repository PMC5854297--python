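import numpy as np
import pytest

from resdyn.generate import BenchmarkSpec, build_benchmark, fixture_worked_examples
from resdyn.landscape import Landscape, Site


@pytest.fixture
def worked4():
    return fixture_worked_examples("worked4")


@pytest.fixture
def worked3():
    return fixture_worked_examples("worked3")


@pytest.fixture(scope="session")
def small9():
    """One fixed small-grid benchmark instance (non-correlated threat)."""
    return build_benchmark(BenchmarkSpec("small9", seed=7))


def random_landscape(seed: int, n: int = 5, n_targets: int = 2, blm: float = 0.0) -> Landscape:
    """Small random instance for property checks (no geometry)."""
    rng = np.random.default_rng(seed)
    hab = rng.uniform(0, 10, (n, n_targets))
    mu = rng.uniform(0.05, 0.6, n)
    costs = rng.uniform(0.5, 2.0, n)
    sites = [
        Site(i + 1, float(costs[i]), tuple(hab[i]), float(mu[i]), perimeter=4.0)
        for i in range(n)
    ]
    return Landscape(sites, targets=0.5 * hab.sum(axis=0), blm=blm)
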