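"""Purchase-order optimization for a planned reserve network.

A minimum-set solution computed from a static snapshot still has to be bought
over several years, during which unprotected sites may be converted.  The
order of purchase therefore matters.  Given a reference yearly budget ``m_B``,
the purchase year of the i-th site in a sequence is the ceiling of the
cumulative cost over ``m_B``; a site contributes its habitat only if it
survives until then, which happens with probability ``(1 - mu)^(t_buy - 1)``.
The expected effective abundance of a sequence is this survival-discounted
abundance capped at the target, and sequences are ranked either by the sum
over habitats (utilitarian) or by the worst habitat (egalitarian).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence as Seq

import numpy as np

from .landscape import Landscape

__all__ = [
    "Sequence",
    "purchase_years",
    "expected_abundance",
    "expected_effective_abundance",
    "order_objective",
    "optimal_ordering",
]


@dataclass(frozen=True)
class Sequence:
    """An ordered purchase plan with its reference yearly budget."""

    sites: tuple[int, ...]
    m_B: float

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("sequence contains duplicate sites")
        if self.m_B <= 0:
            raise ValueError("m_B must be > 0")


def purchase_years(sequence: Iterable[int], landscape: Landscape, m_B: float) -> list[int]:
    """Projected purchase year of each site: ceil(cumulative cost / m_B)."""
    if m_B <= 0:
        raise ValueError("m_B must be > 0")
    years = []
    cum = 0.0
    for sid in sequence:
        cum += landscape.site(sid).cost
        years.append(int(math.ceil(cum / m_B - 1e-12)))
    return years


def expected_abundance(
    sequence: Seq[int],
    landscape: Landscape,
    j: int,
    m_B: float,
    base_abundance: float = 0.0,
) -> float:
    """Survival-discounted expected abundance of habitat ``j`` for a sequence.

    ``base_abundance`` adds habitat already secured (e.g. sites reserved in
    earlier periods), which is certain and not discounted.
    """
    col = j - 1
    if not 0 <= col < landscape.n_targets:
        raise IndexError(f"habitat index {j} outside 1..{landscape.n_targets}")
    total = base_abundance
    for sid, year in zip(sequence, purchase_years(sequence, landscape, m_B)):
        site = landscape.site(sid)
        total += (1.0 - site.mu) ** (year - 1) * site.habitat[col]
    return total


def expected_effective_abundance(
    sequence: Seq[int],
    landscape: Landscape,
    j: int,
    m_B: float,
    base_abundance: float = 0.0,
) -> float:
    """Expected abundance capped at the target: ``min(H_j, E[A_j])``."""
    return min(
        float(landscape.targets[j - 1]),
        expected_abundance(sequence, landscape, j, m_B, base_abundance),
    )


def order_objective(
    sequence: Seq[int],
    landscape: Landscape,
    criterion: str = "utilitarian",
    m_B: float = 1.0,
    base_abundance: Seq[float] | None = None,
    normalize: bool = False,
) -> float:
    """Score an ordering by its expected effective abundances.

    ``utilitarian`` sums ``E[EA_j]`` over habitats; ``egalitarian`` takes the
    minimum.  ``normalize`` divides each term by its target ``H_j`` (off by
    default: raw area sums are the primary convention).
    """
    if criterion not in ("utilitarian", "egalitarian"):
        raise ValueError(f"unknown criterion {criterion!r}")
    base = base_abundance if base_abundance is not None else [0.0] * landscape.n_targets
    vals = []
    for j in range(1, landscape.n_targets + 1):
        ea = expected_effective_abundance(sequence, landscape, j, m_B, base[j - 1])
        if normalize:
            h = float(landscape.targets[j - 1])
            ea = ea / h if h > 0 else 1.0
        vals.append(ea)
    return float(sum(vals)) if criterion == "utilitarian" else float(min(vals))


_EXHAUSTIVE_LIMIT = 8


def optimal_ordering(
    network: Iterable[int],
    landscape: Landscape,
    criterion: str = "utilitarian",
    m_B: float = 1.0,
    base_abundance: Seq[float] | None = None,
) -> Sequence:
    """Best purchase order of ``network`` under the chosen criterion.

    Exhaustive over all permutations for up to 8 sites; beyond that, greedy
    construction (append the site that maximizes the partial-sequence
    objective) followed by pairwise-swap hill climbing.  Deterministic: ties
    break toward the input order (for an unordered set, ascending site id),
    so with no conversion risk the input ordering is returned unchanged.
    """
    ids = list(dict.fromkeys(network))  # dedup, preserve order
    if not ids:
        raise ValueError("network must be nonempty")

    def score(seq: Seq[int]) -> float:
        return order_objective(seq, landscape, criterion, m_B, base_abundance)

    if len(ids) <= _EXHAUSTIVE_LIMIT:
        best, best_val = None, -math.inf
        for perm in permutations(ids):
            val = score(perm)
            if val > best_val + 1e-12:
                best, best_val = perm, val
        return Sequence(tuple(best), m_B)

    # greedy construction
    remaining = list(ids)
    seq: list[int] = []
    while remaining:
        best_site, best_val = None, -math.inf
        for sid in remaining:
            val = score(seq + [sid])
            if val > best_val + 1e-12:
                best_site, best_val = sid, val
        seq.append(best_site)
        remaining.remove(best_site)

    # pairwise-swap local search
    improved = True
    current = score(seq)
    while improved:
        improved = False
        for i in range(len(seq)):
            for k in range(i + 1, len(seq)):
                seq[i], seq[k] = seq[k], seq[i]
                val = score(seq)
                if val > current + 1e-12:
                    current = val
                    improved = True
                else:
                    seq[i], seq[k] = seq[k], seq[i]
    return Sequence(tuple(seq), m_B)
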