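"""Wash solvent filtering and Pareto ranking (workflow stages 5-6).

Given a chosen crystallization solvent, candidate wash solvents are
annotated with warning flags (boiling/melting point near the wash
temperature, density layer inversion, API more soluble in the wash than
in the crystallization solvent, immiscibility, ICH class 1), screened
against physicochemical and sustainability thresholds, and finally
ranked by non-dominated (Pareto) sorting: minimize API solubility in the
wash solvent while maximizing the solubility of each impurity.  Flags
never remove a candidate from the pool — flagged candidates are simply
excluded from the Pareto ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from pydantic import BaseModel

from .solvents import Solvent

__all__ = [
    "WashFlag",
    "WashFilterConfig",
    "WashCandidate",
    "delta_solubility_class",
    "apply_hard_filters",
    "apply_threshold_filters",
    "pareto_rank",
    "drying_friendliness",
    "viscosity_ratio_report",
    "filter_pipeline",
]


class WashFlag(str, Enum):
    BP_MP_NEAR_WASH_T = "BP_MP_NEAR_WASH_T"
    DENSITY_INVERSION = "DENSITY_INVERSION"
    API_MORE_SOLUBLE_THAN_CRYST = "API_MORE_SOLUBLE_THAN_CRYST"
    IMMISCIBLE = "IMMISCIBLE"
    ICH_REJECT = "ICH_REJECT"
    THRESHOLD_FAIL = "THRESHOLD_FAIL"
    GSK_FAIL = "GSK_FAIL"


class WashFilterConfig(BaseModel):
    """Thresholds for the wash-solvent filters; ``None`` disables a bound.

    Defaults mirror the published screening: wash temperature 22 degC
    with a 10 degC bp/mp exclusion margin, density ratio limit 1.3, and
    (for the threshold filter) melting point < 0 degC, boiling point
    60-130 degC, viscosity < 0.09 Pa.s, vapor pressure < 10 kPa, ICH
    class 3 and all six GSK scores > 3.
    """

    wash_temperature: float = 22.0  # degC
    bp_mp_exclusion_margin: float = 10.0  # degC
    density_ratio_max: float = 1.3
    mp_max: float | None = 0.0  # degC
    bp_range: tuple[float, float] | None = (60.0, 130.0)  # degC
    viscosity_max: float | None = 0.09  # Pa.s
    vapor_pressure_max: float | None = 10_000.0  # Pa
    ich_min_class: int | None = 3
    gsk_min_score: int | None = 3  # scores must be strictly greater
    require_miscible: bool = True
    strict_ich: bool = False  # fail candidates with unknown ICH class


@dataclass(frozen=True)
class WashCandidate:
    """A wash solvent with its solute solubilities and accumulated flags."""

    solvent: Solvent
    api_solubility: float  # g/100 g
    impurity_solubilities: dict[str, float] = field(default_factory=dict)
    miscible_with_cryst: bool = True
    flags: frozenset[WashFlag] = frozenset()

    def __post_init__(self) -> None:
        if self.api_solubility < 0:
            raise ValueError(f"{self.solvent.name}: negative API solubility")
        if any(v < 0 for v in self.impurity_solubilities.values()):
            raise ValueError(f"{self.solvent.name}: negative impurity solubility")

    def with_flags(self, *new_flags: WashFlag) -> "WashCandidate":
        return replace(self, flags=self.flags | frozenset(new_flags))

    @property
    def unflagged(self) -> bool:
        return not self.flags


NEGATIVE = "NEGATIVE"

_CLASS_RECOMMENDATION = {
    1: "1.5-2 equivalent cake volumes (general practice)",
    2: "1.5-2 equivalent cake volumes (general practice)",
    3: "1.5-2 equivalent cake volumes (general practice)",
    4: "1.5-2 equivalent cake volumes (general practice)",
}


def delta_solubility_class(
    api_sol: float, imp_sol: float, impurity_molar_ratio: float | None = None
) -> tuple[int | str, str]:
    """Classify a wash solvent by delta solubility x = impurity - API (g/100 g).

    Classes partition the axis left-closed: 1 for 0 <= x < 1, 2 for
    1 <= x < 10, 3 for 10 <= x < 20, 4 for x >= 20.  x < 0 means the
    impurity is *less* soluble than the API and the cake cannot be fully
    purified by washing: with a low impurity load (< 2 mol %) at least 3
    equivalent cake volumes are recommended, while a high load (>= 2 mol %)
    calls for revising the crystallization or using > 5-6 cake volumes.
    """
    if api_sol < 0 or imp_sol < 0:
        raise ValueError("solubilities must be non-negative")
    x = imp_sol - api_sol
    if x < 0:
        if impurity_molar_ratio is not None and impurity_molar_ratio >= 2.0:
            return NEGATIVE, "revise crystallization or use >5-6 cake volumes"
        return NEGATIVE, ">=3 equivalent cake volumes"
    if x < 1:
        cls = 1
    elif x < 10:
        cls = 2
    elif x < 20:
        cls = 3
    else:
        cls = 4
    return cls, _CLASS_RECOMMENDATION[cls]


def apply_hard_filters(
    candidates: list[WashCandidate],
    cryst_solvent: Solvent,
    cryst_api_sol: float,
    config: WashFilterConfig = WashFilterConfig(),
) -> list[WashCandidate]:
    """Attach the stage-5 warning flags; no candidate is removed.

    Unknown property values pass every filter they cannot be evaluated
    against; the ICH filter is the exception and fails unknowns when
    ``config.strict_ich`` is set.
    """
    out = []
    for cand in candidates:
        s = cand.solvent
        flags: list[WashFlag] = []
        t, margin = config.wash_temperature, config.bp_mp_exclusion_margin
        near_bp = s.boiling_point is not None and abs(s.boiling_point - t) < margin
        near_mp = s.melting_point is not None and abs(s.melting_point - t) < margin
        if near_bp or near_mp:
            flags.append(WashFlag.BP_MP_NEAR_WASH_T)
        if (
            s.density is not None
            and cryst_solvent.density is not None
            and s.density > config.density_ratio_max * cryst_solvent.density
        ):
            flags.append(WashFlag.DENSITY_INVERSION)
        if cand.api_solubility > cryst_api_sol:
            flags.append(WashFlag.API_MORE_SOLUBLE_THAN_CRYST)
        if config.require_miscible and not cand.miscible_with_cryst:
            flags.append(WashFlag.IMMISCIBLE)
        if s.ich_class == 1 or (s.ich_class is None and config.strict_ich):
            flags.append(WashFlag.ICH_REJECT)
        out.append(cand.with_flags(*flags))
    return out


def apply_threshold_filters(
    candidates: list[WashCandidate], config: WashFilterConfig = WashFilterConfig()
) -> list[WashCandidate]:
    """Attach THRESHOLD_FAIL / GSK_FAIL flags for the stage-5 bound checks."""
    out = []
    for cand in candidates:
        s = cand.solvent
        flags: list[WashFlag] = []
        fail = False
        if config.mp_max is not None and s.melting_point is not None:
            fail |= not s.melting_point < config.mp_max
        if config.bp_range is not None and s.boiling_point is not None:
            lo, hi = config.bp_range
            fail |= not lo <= s.boiling_point <= hi
        if config.viscosity_max is not None and s.viscosity is not None:
            fail |= not s.viscosity < config.viscosity_max
        if config.vapor_pressure_max is not None and s.vapor_pressure is not None:
            fail |= not s.vapor_pressure < config.vapor_pressure_max
        if fail:
            flags.append(WashFlag.THRESHOLD_FAIL)
        gsk_fail = False
        if config.gsk_min_score is not None:
            for axis, score in cand.solvent.gsk_scores.items():
                if score is not None and score <= config.gsk_min_score:
                    gsk_fail = True
        if config.ich_min_class is not None:
            if s.ich_class is not None and s.ich_class < config.ich_min_class:
                gsk_fail = True
            elif s.ich_class is None and config.strict_ich:
                gsk_fail = True
        if gsk_fail:
            flags.append(WashFlag.GSK_FAIL)
        out.append(cand.with_flags(*flags))
    return out


def _objectives(cand: WashCandidate, impurities: list[str]) -> np.ndarray:
    # all-minimization convention: API solubility as-is, impurities negated
    return np.array(
        [cand.api_solubility] + [-cand.impurity_solubilities[i] for i in impurities]
    )


def pareto_rank(candidates: list[WashCandidate]) -> list[list[WashCandidate]]:
    """Non-dominated sorting of the *unflagged* candidates into fronts.

    Objectives: minimize API solubility; maximize each impurity
    solubility (each impurity is its own objective).  Uses the fast
    non-dominated sort of NSGA-II as a deterministic sorter over the
    finite pool (no genetic search); within a front, candidates order by
    descending mean impurity solubility, ties by ascending API
    solubility then name — a deterministic substitute for crowding
    distance.
    """
    pool = [c for c in candidates if c.unflagged]
    if not pool:
        return []
    impurities = sorted(pool[0].impurity_solubilities)
    for c in pool:
        if sorted(c.impurity_solubilities) != impurities:
            raise ValueError("all candidates must share the same impurity set")
    objs = np.array([_objectives(c, impurities) for c in pool])
    n = len(pool)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    for i in range(n):
        le = np.all(objs[i] <= objs, axis=1)
        lt = np.any(objs[i] < objs, axis=1)
        dominates = le & lt  # i dominates j
        for j in np.nonzero(dominates)[0]:
            dominated_by[i].append(int(j))
        domination_count += dominates
    fronts: list[list[WashCandidate]] = []
    current = [i for i in range(n) if domination_count[i] == 0]
    while current:
        ordered = sorted(
            current,
            key=lambda i: (
                -float(np.mean([pool[i].impurity_solubilities[k] for k in impurities]))
                if impurities
                else 0.0,
                pool[i].api_solubility,
                pool[i].solvent.name,
            ),
        )
        fronts.append([pool[i] for i in ordered])
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def drying_friendliness(candidates: list[WashCandidate]) -> dict[str, float]:
    """Advisory drying score z(Vp) - z(Tb) - z(dHvap) over the pool.

    Higher is better for drying: volatile, low-boiling, low enthalpy of
    vaporization.  Purely advisory — no published numeric bound exists.
    Candidates missing any of the three properties get NaN.
    """

    def zscores(values: list[float | None]) -> list[float]:
        known = [v for v in values if v is not None]
        mu = float(np.mean(known)) if known else 0.0
        sd = float(np.std(known)) if len(known) > 1 else 1.0
        sd = sd if sd > 0 else 1.0
        return [(v - mu) / sd if v is not None else math.nan for v in values]

    vp = zscores([c.solvent.vapor_pressure for c in candidates])
    tb = zscores([c.solvent.boiling_point for c in candidates])
    dh = zscores([c.solvent.enthalpy_vaporization for c in candidates])
    return {
        c.solvent.name: vp[i] - tb[i] - dh[i] for i, c in enumerate(candidates)
    }


def viscosity_ratio_report(
    candidates: list[WashCandidate], cryst_solvent: Solvent
) -> dict[str, float]:
    """Advisory wash/crystallization viscosity ratios (criterion: similar
    viscosities promote good displacement washing; no hard bound)."""
    out = {}
    for c in candidates:
        if c.solvent.viscosity is not None and cryst_solvent.viscosity:
            out[c.solvent.name] = c.solvent.viscosity / cryst_solvent.viscosity
        else:
            out[c.solvent.name] = math.nan
    return out


def filter_pipeline(
    candidates: list[WashCandidate],
    cryst_solvent: Solvent,
    cryst_api_sol: float,
    config: WashFilterConfig = WashFilterConfig(),
) -> dict[int, list[WashCandidate]]:
    """Apply the cumulative filter levels 1-4 and return each stage's pool.

    Level 1: no filtering.  Level 2: miscibility, density-inversion and
    relative-API-solubility flags (plus ICH rejection).  Level 3: adds
    the physicochemical thresholds.  Level 4: adds the ICH-class and GSK
    score limits.  The unflagged count is non-increasing in the level.
    """
    level1 = list(candidates)
    level2 = apply_hard_filters(level1, cryst_solvent, cryst_api_sol, config)
    phys_only = config.model_copy(update={"ich_min_class": None, "gsk_min_score": None})
    level3 = apply_threshold_filters(level2, phys_only)
    level4 = apply_threshold_filters(level3, config)
    return {1: level1, 2: level2, 3: level3, 4: level4}
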