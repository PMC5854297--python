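"""Synthetic landscape generators.

Three benchmark families are produced, mirroring the study set-ups the rest
of the package is evaluated on:

``small9``
    A 3x3 grid of unit-cost square sites.  Habitat amounts come from a
    Gaussian random field (exponential covariance) sampled at cell centres:
    mean 5 for each of three habitats with (sill, range) = (5, 2), (1, 2) and
    (1.5, 2); the third habitat is non-target filler.  Targets are 50% of the
    realized totals of habitats 1 and 2, the yearly budget is a constant 1
    and BLM = 0.
``large880``
    The same habitat model on an 880-site Voronoi tessellation of a square,
    with habitat-linked costs c(s) = $4,000 * (h1(s) + h2(s)) and a
    stochastic yearly budget ($5M w.p. 2/3, $3M w.p. 1/6, $1M w.p. 1/6).
``ehnwr``
    A five-habitat landscape in the style of the Everglades Headwaters NWR
    extension: per-habitat field parameters from the published table,
    per-site amounts normalized to the site area, category-based conversion
    rates and exponential per-area costs (mean $25,242 per km^2).

Two tiny worked examples (``worked4``, ``worked3``) used throughout the test
suite are also built here.  All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely import STRtree
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .evaluation import BudgetModel
from .landscape import Landscape, SharedBoundaries, Site

__all__ = [
    "GRFSpec",
    "Geometry",
    "BenchmarkSpec",
    "simulate_grf_habitats",
    "grid_geometry",
    "voronoi_landscape",
    "assign_conversion_rates",
    "assign_costs",
    "normalize_to_area",
    "fixture_worked_examples",
    "build_benchmark",
]


@dataclass(frozen=True)
class GRFSpec:
    """Parameters of one Gaussian-random-field habitat layer.

    The covariance between two sites at distance ``d`` is
    ``sill * exp(-d / range_)``.  When ``variance`` is given, the sill is on a
    normalized scale and the field is rescaled so its marginal variance equals
    ``variance`` (the convention of the five-habitat benchmark's parameter
    table); otherwise the sill itself is the marginal variance.
    """

    mean: float
    sill: float
    range_: float
    variance: float | None = None
    covariance: str = "exponential"

    def __post_init__(self) -> None:
        if self.sill <= 0 or self.range_ <= 0:
            raise ValueError("sill and range must be > 0")
        if self.covariance != "exponential":
            raise ValueError("only the exponential covariance kernel is supported")


@dataclass
class Geometry:
    """Planar tessellation: centroids, polygons and measured boundary lengths."""

    centroids: np.ndarray  # (n, 2)
    polygons: list[Polygon]
    areas: np.ndarray
    perimeters: np.ndarray
    shared: dict[tuple[int, int], float]  # 0-based index pairs, i < j

    @property
    def n(self) -> int:
        return len(self.polygons)

    def boundaries_for_ids(self, ids: Sequence[int]) -> SharedBoundaries:
        sb = SharedBoundaries()
        for (i, j), length in self.shared.items():
            sb.set(ids[i], ids[j], length)
        return sb


def simulate_grf_habitats(
    centroids: np.ndarray,
    specs: Sequence[GRFSpec],
    seed: int,
) -> np.ndarray:
    """Draw one habitat matrix (n_sites x n_habitats) from Gaussian fields.

    Each column is an independent draw from a multivariate normal with mean
    ``spec.mean`` and exponential covariance evaluated at the centroids.
    Negative values are truncated to 0 (habitat amounts are areas).
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one centroid of dimension >= 1")
    rng = np.random.default_rng(seed)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    n = pts.shape[0]
    out = np.empty((n, len(specs)))
    for k, spec in enumerate(specs):
        cov = spec.sill * np.exp(-d / spec.range_)
        chol = None
        jitter = 1e-12 * spec.sill
        for _ in range(8):
            try:
                chol = np.linalg.cholesky(cov + jitter * np.eye(n))
                break
            except np.linalg.LinAlgError:
                jitter *= 10.0
        if chol is None:
            raise np.linalg.LinAlgError(
                f"habitat {k + 1}: covariance not positive definite even after jitter"
            )
        z = chol @ rng.standard_normal(n)
        if spec.variance is not None:
            z *= math.sqrt(spec.variance / spec.sill)
        out[:, k] = np.maximum(0.0, spec.mean + z)
    return out


def grid_geometry(rows: int, cols: int, cell: float = 1.0) -> Geometry:
    """Regular grid of square sites (row-major order)."""
    polys: list[Polygon] = []
    centers = []
    shared: dict[tuple[int, int], float] = {}
    for r in range(rows):
        for c in range(cols):
            polys.append(box(c * cell, r * cell, (c + 1) * cell, (r + 1) * cell))
            centers.append(((c + 0.5) * cell, (r + 0.5) * cell))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                shared[(i, i + 1)] = cell
            if r + 1 < rows:
                shared[(i, i + cols)] = cell
    n = rows * cols
    return Geometry(
        centroids=np.array(centers),
        polygons=polys,
        areas=np.full(n, cell * cell),
        perimeters=np.full(n, 4.0 * cell),
        shared=shared,
    )


def voronoi_landscape(
    n_sites: int,
    extent: tuple[float, float],
    seed: int,
) -> Geometry:
    """Voronoi tessellation of a rectangle from uniform random centroids.

    Cells are clipped to the extent; perimeters, areas and pairwise shared
    boundary lengths are measured on the clipped polygons, so selecting every
    site reproduces the extent's own perimeter and area exactly.
    Degenerate centroid draws (e.g. collinear) are re-seeded with a warning.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    width, height = extent
    frame = box(0.0, 0.0, width, height)
    rng_seed = seed
    for attempt in range(6):
        rng = np.random.default_rng(rng_seed)
        pts = np.column_stack(
            [rng.uniform(0, width, n_sites), rng.uniform(0, height, n_sites)]
        )
        if n_sites == 1:
            return Geometry(
                centroids=pts,
                polygons=[frame],
                areas=np.array([frame.area]),
                perimeters=np.array([frame.length]),
                shared={},
            )
        try:
            cells = voronoi_diagram(MultiPoint(pts.tolist()), envelope=frame)
            clipped = [g.intersection(frame) for g in cells.geoms]
            tree = STRtree(clipped)
            polys: list[Polygon | None] = [None] * n_sites
            for i, (x, y) in enumerate(pts):
                p = Point(x, y)
                for idx in tree.query(p):
                    if clipped[idx].covers(p):
                        polys[i] = clipped[idx]
                        break
            if any(p is None or p.is_empty or not isinstance(p, Polygon) for p in polys):
                raise ValueError("could not match every centroid to a Voronoi cell")
        except Exception as exc:  # degenerate input: reseed
            warnings.warn(
                f"degenerate Voronoi draw ({exc}); reseeding (attempt {attempt + 1})",
                stacklevel=2,
            )
            rng_seed = rng_seed * 6364136223846793005 % (2**31 - 1) + 1
            continue
        shared: dict[tuple[int, int], float] = {}
        tree = STRtree(polys)
        for i, poly in enumerate(polys):
            for j in tree.query(poly):
                j = int(j)
                if j <= i:
                    continue
                length = poly.intersection(polys[j]).length
                if length > 1e-12:
                    shared[(i, j)] = float(length)
        return Geometry(
            centroids=pts,
            polygons=list(polys),
            areas=np.array([p.area for p in polys]),
            perimeters=np.array([p.length for p in polys]),
            shared=shared,
        )
    raise RuntimeError("failed to build a non-degenerate Voronoi landscape")


#: per-category uniform mu ranges for the category conversion mode.  The
#: source data behind the original category distributions is not public;
#: these synthetic defaults order threat by habitat content and are
#: configurable.
DEFAULT_CATEGORY_RANGES: tuple[tuple[float, float], ...] = (
    (0.001, 0.1),
    (0.01, 0.3),
    (0.02, 0.6),
)


def assign_conversion_rates(
    habitats: np.ndarray,
    mode: str,
    seed: int,
    n_targets: int | None = None,
    areas: np.ndarray | None = None,
    category_ranges: Sequence[tuple[float, float]] = DEFAULT_CATEGORY_RANGES,
) -> np.ndarray:
    """Draw per-site conversion probabilities.

    ``noncorrelated``
        mu ~ U[0.01, 0.3], independent of habitat content.
    ``correlated``
        Sites whose first-habitat share of the site's total habitat exceeds
        5% draw mu ~ U[0.02, 0.6]; the rest draw mu ~ U[0.001, 0.1], so the
        richest first-habitat sites are the most threatened.
    ``category``
        Sites fall into three categories by the fraction of their area
        covered by target habitats (< 30%, 30-60%, >= 60%); each category has
        its own uniform range (``category_ranges``).  Requires ``areas`` and
        ``n_targets``.
    """
    hab = np.asarray(habitats, dtype=float)
    n = hab.shape[0]
    rng = np.random.default_rng(seed)
    if mode == "noncorrelated":
        return rng.uniform(0.01, 0.3, n)
    if mode == "correlated":
        totals = hab.sum(axis=1)
        share = np.divide(hab[:, 0], totals, out=np.zeros(n), where=totals > 0)
        mu = np.where(
            share > 0.05,
            rng.uniform(0.02, 0.6, n),
            rng.uniform(0.001, 0.1, n),
        )
        return mu
    if mode == "category":
        if areas is None or n_targets is None:
            raise ValueError("category mode requires site areas and n_targets")
        frac = hab[:, :n_targets].sum(axis=1) / np.asarray(areas, dtype=float)
        cat = np.digitize(frac, [0.3, 0.6])
        mu = np.empty(n)
        for c, (lo, hi) in enumerate(category_ranges):
            mask = cat == c
            mu[mask] = rng.uniform(lo, hi, int(mask.sum()))
        return mu
    raise ValueError(f"unknown conversion mode {mode!r}")


def assign_costs(
    habitats: np.ndarray,
    model: str,
    seed: int,
    areas_km2: np.ndarray | None = None,
    cost_per_unit: float = 4000.0,
    mean_cost_per_km2: float = 25242.0,
) -> np.ndarray:
    """Draw per-site acquisition costs.

    ``unit`` gives every site cost 1; ``habitat_linked`` prices a site at
    ``cost_per_unit * (h1 + h2)``; ``exponential_area`` draws a per-km^2 land
    price from an exponential distribution (mean ``mean_cost_per_km2``) and
    multiplies by the site's area.
    """
    hab = np.asarray(habitats, dtype=float)
    n = hab.shape[0]
    if model == "unit":
        return np.ones(n)
    if model == "habitat_linked":
        return cost_per_unit * (hab[:, 0] + hab[:, 1])
    if model == "exponential_area":
        if areas_km2 is None:
            raise ValueError("exponential_area model requires site areas")
        rng = np.random.default_rng(seed)
        return np.asarray(areas_km2, dtype=float) * rng.exponential(mean_cost_per_km2, n)
    raise ValueError(f"unknown cost model {model!r}")


def normalize_to_area(habitats: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Proportionally rescale each site's habitats so their sum <= site area."""
    hab = np.asarray(habitats, dtype=float).copy()
    totals = hab.sum(axis=1)
    over = totals > np.asarray(areas, dtype=float)
    factor = np.divide(areas, totals, out=np.ones_like(totals), where=totals > 0)
    hab[over] *= factor[over, None]
    return hab


def fixture_worked_examples(kind: str) -> Landscape:
    """The two in-text miniature examples.

    ``worked4``: four unit-cost sites with a single habitat in amounts
    (6, 2, 4, 3) and target 7, so {s1,s3} and {s3,s4} are both minimum-cost
    solutions of cost 2.  ``worked3``: three unit-cost sites where any pair
    meets the targets.  Both use a yearly budget of 1 and BLM = 0; conversion
    probabilities default to 0.5 (the examples hold for any mu in (0, 1)).
    """
    if kind == "worked4":
        amounts = (6.0, 2.0, 4.0, 3.0)
        sites = [
            Site(id=i + 1, cost=1.0, habitat=(a,), mu=0.5, perimeter=4.0)
            for i, a in enumerate(amounts)
        ]
        return Landscape(sites, targets=(7.0,), blm=0.0)
    if kind == "worked3":
        sites = [
            Site(id=i + 1, cost=1.0, habitat=(1.0,), mu=0.5, perimeter=4.0)
            for i in range(3)
        ]
        return Landscape(sites, targets=(2.0,), blm=0.0)
    raise ValueError(f"unknown worked example {kind!r}")


_SMALL_SPECS = (
    GRFSpec(mean=5.0, sill=5.0, range_=2.0),
    GRFSpec(mean=5.0, sill=1.0, range_=2.0),
    GRFSpec(mean=5.0, sill=1.5, range_=2.0),
)

_EHNWR_SPECS = (
    GRFSpec(mean=51582.0, sill=0.954, range_=0.888, variance=153047.0),
    GRFSpec(mean=29836.0, sill=0.931, range_=0.713, variance=101547.0),
    GRFSpec(mean=71027.0, sill=1.0, range_=0.58, variance=143387.0),
    GRFSpec(mean=109553.0, sill=1.0, range_=0.693, variance=223443.0),
    GRFSpec(mean=133791.0, sill=1.0, range_=0.693, variance=186932.0),
    GRFSpec(mean=604207.0, sill=0.986, range_=0.793, variance=351229.0),  # non-key
)

_EHNWR_TARGET_FRACTIONS = (0.67, 0.388, 0.26, 0.32, 0.388)

_STOCHASTIC_BUDGET = BudgetModel.discrete(
    [5_000_000.0, 3_000_000.0, 1_000_000.0], [2 / 3, 1 / 6, 1 / 6]
)


@dataclass
class BenchmarkSpec:
    """Recipe for one benchmark instance; unset fields take per-kind defaults."""

    kind: str  # small9 | large880 | ehnwr | worked4 | worked3
    n_sites: int | None = None
    seed: int = 0
    conversion_mode: str | None = None
    cost_model: str | None = None
    blm: float = 0.0
    habitat_scale: float | None = None
    target_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in {"small9", "large880", "ehnwr", "worked4", "worked3"}:
            raise ValueError(f"unknown benchmark kind {self.kind!r}")


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def build_benchmark(spec: BenchmarkSpec) -> tuple[Landscape, BudgetModel]:
    """Materialize a benchmark instance and its budget model from a spec."""
    if spec.kind in ("worked4", "worked3"):
        return fixture_worked_examples(spec.kind), BudgetModel.constant(1.0)

    hab_seed, mu_seed, cost_seed, geom_seed = _sub_seeds(spec.seed, 4)

    if spec.kind == "small9":
        geom = grid_geometry(3, 3)
        scale = spec.habitat_scale if spec.habitat_scale is not None else 1.0
        hab = simulate_grf_habitats(geom.centroids, _SMALL_SPECS, hab_seed) * scale
        mode = spec.conversion_mode or "noncorrelated"
        mu = assign_conversion_rates(hab, mode, mu_seed, n_targets=2, areas=geom.areas)
        costs = assign_costs(hab, spec.cost_model or "unit", cost_seed)
        n_targets = 2
        targets = spec.target_fraction * hab[:, :n_targets].sum(axis=0)
        budget = BudgetModel.constant(1.0)
    elif spec.kind == "large880":
        n = spec.n_sites or 880
        side = math.sqrt(n)  # mean cell area 1, matching the habitat field's scale
        geom = voronoi_landscape(n, (side, side), geom_seed)
        scale = spec.habitat_scale if spec.habitat_scale is not None else 5.4
        hab = simulate_grf_habitats(geom.centroids, _SMALL_SPECS, hab_seed) * scale
        mode = spec.conversion_mode or "noncorrelated"
        mu = assign_conversion_rates(hab, mode, mu_seed, n_targets=2, areas=geom.areas)
        costs = assign_costs(hab, spec.cost_model or "habitat_linked", cost_seed)
        n_targets = 2
        targets = spec.target_fraction * hab[:, :n_targets].sum(axis=0)
        budget = _STOCHASTIC_BUDGET
    elif spec.kind == "ehnwr":
        n = spec.n_sites or 880
        side_m = math.sqrt(n * 1e6)  # mean site area 1 km^2, in m^2 units
        geom = voronoi_landscape(n, (side_m, side_m), geom_seed)
        # field ranges are on a normalized [0,1] coordinate scale
        hab = simulate_grf_habitats(geom.centroids / side_m, _EHNWR_SPECS, hab_seed)
        hab = normalize_to_area(hab, geom.areas)
        n_targets = 5
        mu = assign_conversion_rates(
            hab, spec.conversion_mode or "category", mu_seed, n_targets=n_targets,
            areas=geom.areas,
        )
        costs = assign_costs(
            hab, spec.cost_model or "exponential_area", cost_seed,
            areas_km2=geom.areas / 1e6,
        )
        targets = np.array(_EHNWR_TARGET_FRACTIONS) * hab[:, :n_targets].sum(axis=0)
        budget = _STOCHASTIC_BUDGET
    else:  # pragma: no cover - guarded by BenchmarkSpec
        raise ValueError(spec.kind)

    ids = list(range(1, geom.n + 1))
    sites = [
        Site(
            id=ids[i],
            cost=float(costs[i]),
            habitat=tuple(hab[i]),
            mu=float(min(1.0, max(0.0, mu[i]))),
            perimeter=float(geom.perimeters[i]),
        )
        for i in range(geom.n)
    ]
    landscape = Landscape(
        sites,
        boundaries=geom.boundaries_for_ids(ids),
        targets=targets,
        blm=spec.blm,
    )
    landscape.geometry = geom  # kept for geometric oracles and GeoJSON export
    return landscape, budget
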