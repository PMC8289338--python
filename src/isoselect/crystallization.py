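"""Crystallization solvent ranking (workflow stages 1-4).

Candidates are scored by the mass balance of a cooling crystallization:
the API dissolved at the hot loading crystallizes out down to the cold
(isolation-temperature) solubility, giving a returned product mass, a
percentage yield, and a solvent consumption ratio (g solvent per g
product).  Candidates are placed on a 3x3 yield x solvent-volume grid and
ranked by a configurable category order; safety (ICH class 1) and the
practical suspension-density window (3.5-10 g solvent per g API) act as
exclusion/demotion rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .solvents import Solvent

__all__ = [
    "CrystallizationCandidate",
    "RankingGrid",
    "RankedCandidate",
    "CrystallizationRanking",
    "crystallization_yield",
    "assign_category",
    "rank_crystallization_solvents",
]


@dataclass(frozen=True)
class CrystallizationCandidate:
    """A solvent with its hot and cold API loadings (g API per g solvent)."""

    solvent: Solvent
    hot_loading: float  # g API dissolved per g solvent at dissolution T
    cold_solubility: float  # g API per g solvent at isolation T
    solvent_mass: float = 100.0  # g; the ranking basis

    def __post_init__(self) -> None:
        if not self.hot_loading >= self.cold_solubility >= 0:
            raise ValueError(
                f"{self.solvent.name}: require hot_loading >= cold_solubility >= 0"
            )
        if self.solvent_mass <= 0:
            raise ValueError(f"{self.solvent.name}: solvent_mass must be > 0")


@dataclass(frozen=True)
class RankingGrid:
    """The 3x3 yield/solvent-volume category grid.

    ``yield_band_edges`` are descending % thresholds, ``volume_band_edges``
    ascending g-solvent/g-product thresholds; both are left-closed at the
    printed edge.  The numeric edges are configurable defaults (the
    published grid is a color figure); the category order and the
    3.5/10 g/g suspension limits are the printed rules.
    """

    yield_band_edges: tuple[float, float] = (90.0, 70.0)
    volume_band_edges: tuple[float, float] = (10.0, 20.0)
    category_order: tuple[int, ...] = (1, 4, 7, 2, 5, 8, 3, 6, 9)
    colors: dict[int, str] = field(
        default_factory=lambda: {
            1: "green", 4: "green",
            2: "orange", 5: "orange", 7: "orange",
            3: "red", 6: "red", 8: "red", 9: "red",
        }
    )

    def __post_init__(self) -> None:
        if not self.yield_band_edges[0] > self.yield_band_edges[1]:
            raise ValueError("yield_band_edges must be strictly descending")
        if not self.volume_band_edges[0] < self.volume_band_edges[1]:
            raise ValueError("volume_band_edges must be strictly ascending")
        if sorted(self.category_order) != list(range(1, 10)):
            raise ValueError("category_order must be a permutation of 1..9")


def crystallization_yield(
    candidate: CrystallizationCandidate,
) -> tuple[float, float, float]:
    """Return (return_mass g, yield %, solvent_ratio g solvent / g product).

    return_mass = (hot - cold) * solvent_mass; yield = 100 * (hot - cold) / hot.
    A candidate with cold == hot returns nothing: yield 0 and an infinite
    solvent ratio.
    """
    if candidate.hot_loading == 0:
        raise ValueError(f"{candidate.solvent.name}: hot loading is zero")
    return_mass = (candidate.hot_loading - candidate.cold_solubility) * candidate.solvent_mass
    yield_pct = 100.0 * (candidate.hot_loading - candidate.cold_solubility) / candidate.hot_loading
    ratio = candidate.solvent_mass / return_mass if return_mass > 0 else math.inf
    return return_mass, yield_pct, ratio


def assign_category(
    yield_pct: float, solvent_ratio: float, grid: RankingGrid = RankingGrid()
) -> tuple[int, str]:
    """Place (yield %, solvent ratio) on the grid -> (category 1..9, color)."""
    hi, lo = grid.yield_band_edges
    yield_band = 0 if yield_pct >= hi else (1 if yield_pct >= lo else 2)
    low, high = grid.volume_band_edges
    volume_band = 0 if solvent_ratio < low else (1 if solvent_ratio < high else 2)
    category = 3 * volume_band + yield_band + 1
    return category, grid.colors.get(category, "unknown")


@dataclass(frozen=True)
class RankedCandidate:
    candidate: CrystallizationCandidate
    return_mass: float
    yield_pct: float
    solvent_ratio: float
    category: int
    color: str
    demoted: bool = False  # above the preferred max suspension ratio


@dataclass(frozen=True)
class CrystallizationRanking:
    ranked: tuple[RankedCandidate, ...]
    excluded: tuple[tuple[CrystallizationCandidate, str], ...]


def rank_crystallization_solvents(
    candidates: list[CrystallizationCandidate],
    grid: RankingGrid = RankingGrid(),
    min_ratio: float = 3.5,
    max_ratio: float = 10.0,
) -> CrystallizationRanking:
    """Rank crystallization candidates on the category grid.

    ICH-class-1 solvents are excluded outright.  Candidates below
    ``min_ratio`` g solvent per g product (an impractically dense, pasty
    suspension) are excluded; candidates above ``max_ratio`` are kept but
    flagged as demoted (dilute suspension) — an annotation, not a sort
    key, since the grid's volume bands already penalize dilute processes
    and the printed category order takes precedence.  Survivors sort by
    category-order position, ties broken by descending yield, then
    ascending solvent ratio, then name.  ICH class 2 survivors are kept
    (annotated by their ICH class on the solvent) but are not favored.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    excluded: list[tuple[CrystallizationCandidate, str]] = []
    scored: list[RankedCandidate] = []
    for cand in candidates:
        if cand.solvent.ich_class == 1:
            excluded.append((cand, "ICH class 1 solvent rejected"))
            continue
        return_mass, yield_pct, ratio = crystallization_yield(cand)
        if ratio < min_ratio:
            excluded.append(
                (cand, f"suspension too dense: {ratio:.2f} g/g < {min_ratio} g/g")
            )
            continue
        category, color = assign_category(yield_pct, ratio, grid)
        scored.append(
            RankedCandidate(
                cand, return_mass, yield_pct, ratio, category, color,
                demoted=ratio > max_ratio,
            )
        )
    position = {cat: i for i, cat in enumerate(grid.category_order)}
    scored.sort(
        key=lambda r: (
            position[r.category],
            -r.yield_pct,
            r.solvent_ratio,
            r.candidate.solvent.name,
        )
    )
    return CrystallizationRanking(tuple(scored), tuple(excluded))
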