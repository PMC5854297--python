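"""Core data model for dynamic reserve design.

A :class:`Landscape` is a set of purchasable sites, each carrying an
acquisition cost ``c(s)``, a vector of habitat amounts ``h_j(s)`` for the
``J`` target habitats (plus optional non-target filler columns), a per-period
conversion probability ``mu(s)`` and polygon boundary lengths.  The planning
problem is to assemble, over time, a reserve network whose habitat abundances
meet the targets ``H_1..H_J`` at minimal *extended cost*

    c(N) = sum_{s in N} c(s) + Penalty(N) + BLM * Boundary(N),

where ``Penalty`` is 0 when every target is met and a large constant ``alpha``
otherwise, and ``Boundary`` is the outer boundary length of the network
(total perimeter minus twice the shared edges).  ``BLM`` (boundary length
modifier) trades compactness against money, exactly as in minimum-set
reserve-selection software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Site",
    "SharedBoundaries",
    "Landscape",
    "ReserveState",
]


@dataclass(frozen=True)
class Site:
    """One planning unit.

    Parameters
    ----------
    id:
        Integer label; arbitrary non-negative, need not be dense.
    cost:
        Acquisition cost ``c(s)`` in currency units, >= 0.
    habitat:
        Amounts ``(h_1(s), ..., h_J(s)[, h_nontarget...])`` in area units.
        Columns beyond the landscape's target count are non-target filler and
        are ignored by all scoring.
    mu:
        Probability in [0, 1] that the site, if left unreserved, is
        irreversibly converted at the end of any given period.
    perimeter:
        Boundary length ``pi_s`` of the site's polygon.
    """

    id: int
    cost: float
    habitat: tuple[float, ...]
    mu: float
    perimeter: float = 0.0

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"site {self.id}: cost must be >= 0, got {self.cost}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"site {self.id}: mu must lie in [0, 1], got {self.mu}")
        if any(h < 0 for h in self.habitat):
            raise ValueError(f"site {self.id}: habitat amounts must be >= 0")
        if self.perimeter < 0:
            raise ValueError(f"site {self.id}: perimeter must be >= 0")
        object.__setattr__(self, "habitat", tuple(float(h) for h in self.habitat))


class SharedBoundaries:
    """Sparse symmetric map of shared boundary lengths ``pi_{s1,s2}``.

    Missing pairs have length 0.  Keys are unordered site-id pairs.
    """

    def __init__(self, lengths: Mapping[tuple[int, int], float] | None = None):
        self._lengths: dict[tuple[int, int], float] = {}
        if lengths:
            for (a, b), val in lengths.items():
                self.set(a, b, val)

    @staticmethod
    def _key(a: int, b: int) -> tuple[int, int]:
        if a == b:
            raise ValueError(f"a site ({a}) cannot share a boundary with itself")
        return (a, b) if a < b else (b, a)

    def set(self, a: int, b: int, length: float) -> None:
        if length < 0:
            raise ValueError(f"shared boundary ({a},{b}) must be >= 0, got {length}")
        if length > 0:
            self._lengths[self._key(a, b)] = float(length)

    def get(self, a: int, b: int) -> float:
        return self._lengths.get(self._key(a, b), 0.0)

    def items(self) -> Iterator[tuple[tuple[int, int], float]]:
        return iter(self._lengths.items())

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SharedBoundaries):
            return NotImplemented
        return self._lengths == other._lengths


class Landscape:
    """Immutable problem instance: sites, geometry, targets and penalties.

    Parameters
    ----------
    sites:
        Iterable of :class:`Site` with distinct ids.
    boundaries:
        Shared boundary lengths; ``None`` means no two sites touch.
    targets:
        Habitat targets ``H_1..H_J`` (area units).  Habitat columns beyond
        ``J`` are treated as non-target filler.
    blm:
        Boundary length modifier, >= 0.
    spf:
        Penalty factor applied to target shortfalls in the static (one-shot)
        objective.  Scalar or length-``J`` vector.
    alpha:
        Extended-cost penalty for missing any target.  Defaults to twice the
        total cost of the landscape, computed at construction and frozen.
    initial_reserve:
        Site ids already protected at time 0.
    """

    def __init__(
        self,
        sites: Iterable[Site],
        boundaries: SharedBoundaries | None = None,
        targets: Iterable[float] = (),
        blm: float = 0.0,
        spf: float | Iterable[float] = 1e6,
        alpha: float | None = None,
        initial_reserve: Iterable[int] = (),
    ):
        self.sites: tuple[Site, ...] = tuple(sorted(sites, key=lambda s: s.id))
        if not self.sites:
            raise ValueError("a landscape needs at least one site")
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")
        self._ids: tuple[int, ...] = tuple(ids)
        self._index: dict[int, int] = {sid: i for i, sid in enumerate(ids)}
        self._sites_by_id: dict[int, Site] = {s.id: s for s in self.sites}

        self.targets: np.ndarray = np.asarray(list(targets), dtype=float)
        if np.any(self.targets < 0):
            raise ValueError("targets must be >= 0")
        n_hab = min(len(s.habitat) for s in self.sites)
        if self.n_targets > n_hab:
            raise ValueError(
                f"{self.n_targets} targets but sites carry only {n_hab} habitat columns"
            )

        if blm < 0:
            raise ValueError("blm must be >= 0")
        self.blm = float(blm)
        spf_arr = np.asarray(spf, dtype=float)
        if spf_arr.ndim == 0:
            spf_arr = np.full(self.n_targets, float(spf_arr))
        if len(spf_arr) != self.n_targets:
            raise ValueError("spf vector length must equal the number of targets")
        if np.any(spf_arr <= 0):
            raise ValueError("spf must be > 0")
        self.spf: np.ndarray = spf_arr

        total_cost = float(sum(s.cost for s in self.sites))
        self.alpha = float(alpha) if alpha is not None else 2.0 * total_cost
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")

        self.initial_reserve: frozenset[int] = frozenset(initial_reserve)
        unknown = self.initial_reserve - set(ids)
        if unknown:
            raise ValueError(f"initial_reserve references unknown site ids {sorted(unknown)}")

        self.boundaries = boundaries if boundaries is not None else SharedBoundaries()
        self._adjacency: dict[int, list[tuple[int, float]]] = {sid: [] for sid in ids}
        for (a, b), length in self.boundaries.items():
            if a not in self._index or b not in self._index:
                raise ValueError(f"shared boundary ({a},{b}) references an unknown site id")
            cap = min(self._sites_by_id[a].perimeter, self._sites_by_id[b].perimeter)
            if length > cap * (1 + 1e-9):
                raise ValueError(
                    f"shared boundary ({a},{b})={length} exceeds a site perimeter ({cap})"
                )
            self._adjacency[a].append((b, length))
            self._adjacency[b].append((a, length))

        # cached arrays, aligned with self._ids
        self.cost_array = np.array([s.cost for s in self.sites])
        self.mu_array = np.array([s.mu for s in self.sites])
        self.perimeter_array = np.array([s.perimeter for s in self.sites])
        self.habitat_matrix = np.array([s.habitat[:n_hab] for s in self.sites])

        for j in range(self.n_targets):
            total = float(self.habitat_matrix[:, j].sum())
            if self.targets[j] > total * (1 + 1e-12):
                warnings.warn(
                    f"target H_{j + 1}={self.targets[j]} exceeds the landscape total "
                    f"{total}; it is unattainable even at t=0",
                    stacklevel=2,
                )

    # -- basic introspection ------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def site_ids(self) -> frozenset[int]:
        return frozenset(self._ids)

    @property
    def ordered_ids(self) -> tuple[int, ...]:
        return self._ids

    def site(self, site_id: int) -> Site:
        try:
            return self._sites_by_id[site_id]
        except KeyError:
            raise KeyError(f"unknown site id {site_id}") from None

    def index_of(self, site_id: int) -> int:
        try:
            return self._index[site_id]
        except KeyError:
            raise KeyError(f"unknown site id {site_id}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Landscape):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.boundaries == other.boundaries
            and np.array_equal(self.targets, other.targets)
            and self.blm == other.blm
            and np.array_equal(self.spf, other.spf)
            and self.alpha == other.alpha
            and self.initial_reserve == other.initial_reserve
        )

    # -- accounting ---------------------------------------------------------

    def _check_network(self, network: Iterable[int]) -> list[int]:
        ids = list(network)
        for sid in ids:
            if sid not in self._index:
                raise KeyError(f"unknown site id {sid}")
        return ids

    def _check_habitat_index(self, j: int) -> int:
        if not 1 <= j <= self.n_targets:
            raise IndexError(f"habitat index {j} outside 1..{self.n_targets}")
        return j - 1

    def abundance(self, network: Iterable[int], j: int) -> float:
        """Total amount ``A_j(N)`` of target habitat ``j`` (1-based) in ``network``."""
        col = self._check_habitat_index(j)
        return float(sum(self._sites_by_id[s].habitat[col] for s in self._check_network(network)))

    def effective_abundance(self, network: Iterable[int], j: int) -> float:
        """Abundance capped at the target: ``EA_j(N) = min(H_j, A_j(N))``."""
        return min(float(self.targets[j - 1]), self.abundance(network, j))

    def abundance_vector(self, network: Iterable[int]) -> np.ndarray:
        """All target-habitat abundances of ``network`` as a length-``J`` array."""
        ids = self._check_network(network)
        if not ids:
            return np.zeros(self.n_targets)
        rows = [self._index[s] for s in ids]
        return self.habitat_matrix[rows, : self.n_targets].sum(axis=0)

    def targets_met(self, network: Iterable[int]) -> bool:
        """Whether ``network`` meets every habitat target."""
        return bool(np.all(self.abundance_vector(network) >= self.targets - 1e-12))

    def boundary(self, network: Iterable[int]) -> float:
        """Outer boundary length: total perimeter minus twice the shared edges."""
        ids = set(self._check_network(network))
        total = 0.0
        shared2 = 0.0
        for sid in ids:
            total += self._sites_by_id[sid].perimeter
            for other, length in self._adjacency[sid]:
                if other in ids:
                    shared2 += length  # each pair visited from both ends
        return total - shared2

    def total_cost(self, network: Iterable[int]) -> float:
        return float(sum(self._sites_by_id[s].cost for s in self._check_network(network)))

    def penalty(self, network: Iterable[int]) -> float:
        """Shortfall penalty: 0 if all targets met, else ``alpha``."""
        return 0.0 if self.targets_met(network) else self.alpha

    def extended_cost(self, network: Iterable[int]) -> float:
        """Money + shortfall penalty + BLM-weighted boundary of ``network``."""
        ids = list(network)
        return self.total_cost(ids) + self.penalty(ids) + self.blm * self.boundary(ids)

    def feasible(self, purchase: Iterable[int], budget: float) -> bool:
        """Whether the purchase fits the budget: ``sum c(s) <= budget``."""
        return self.total_cost(purchase) <= budget + 1e-9


@dataclass(frozen=True)
class ReserveState:
    """Partition of the sites at one point in time.

    ``available`` is ``S^t`` (still purchasable), ``reserved`` is the network
    built so far.  Converted sites are implied: everything else.
    """

    available: frozenset[int]
    reserved: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "available", frozenset(self.available))
        object.__setattr__(self, "reserved", frozenset(self.reserved))
        if self.available & self.reserved:
            raise ValueError("available and reserved sets must be disjoint")

    def converted(self, all_ids: Iterable[int]) -> frozenset[int]:
        return frozenset(all_ids) - self.available - self.reserved
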