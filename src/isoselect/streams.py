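"""Mass-balance containers shared by the two isolation simulators.

A :class:`Stream` carries component masses for one phase or flow: solid
API crystals, dissolved API, each solvent, and each dissolved impurity.
A :class:`FeedSuspension` is the post-crystallization slurry entering
isolation; :class:`WashSpec` describes the wash schedule in cake void
volumes; :class:`IsolationResult` collects per-stage stream compositions,
yields, impurity removal percentages and risk flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Stream",
    "FeedSuspension",
    "Wash",
    "WashSpec",
    "Checkpoint",
    "IsolationResult",
    "mixture_density",
]


def mixture_density(masses: dict[str, float], densities: dict[str, float]) -> float:
    """Mass-weighted average density (ideal mixing) in g/mL."""
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("mixture has zero mass")
    return sum(m * densities[k] for k, m in masses.items()) / total


@dataclass
class Stream:
    """Component masses (g) of one phase/flow, with derived fractions."""

    api_solid: float = 0.0
    api_dissolved: float = 0.0
    solvents: dict[str, float] = field(default_factory=dict)
    impurities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tol = -1e-12 * max(1.0, self.total_mass)
        for m in self.component_masses().values():
            if m < tol:
                raise ValueError("stream component masses must be non-negative")

    @property
    def total_mass(self) -> float:
        return (
            self.api_solid
            + self.api_dissolved
            + sum(self.solvents.values())
            + sum(self.impurities.values())
        )

    @property
    def api_mass(self) -> float:
        return self.api_solid + self.api_dissolved

    @property
    def api_fraction(self) -> float:
        """API (solid + dissolved) mass fraction of the stream."""
        return self.api_mass / self.total_mass

    def impurity_fraction(self, name: str) -> float:
        return self.impurities.get(name, 0.0) / self.total_mass

    def component_masses(self) -> dict[str, float]:
        """Flat component->mass map (solvents prefixed to avoid clashes)."""
        out = {"api_solid": self.api_solid, "api_dissolved": self.api_dissolved}
        out.update({f"solvent:{k}": v for k, v in self.solvents.items()})
        out.update({f"impurity:{k}": v for k, v in self.impurities.items()})
        return out

    def mass_fractions(self) -> dict[str, float]:
        total = self.total_mass
        if total <= 0:
            raise ValueError("stream has zero total mass")
        return {k: v / total for k, v in self.component_masses().items()}

    def copy(self) -> "Stream":
        return Stream(
            self.api_solid, self.api_dissolved, dict(self.solvents), dict(self.impurities)
        )

    def __add__(self, other: "Stream") -> "Stream":
        solvents = dict(self.solvents)
        for k, v in other.solvents.items():
            solvents[k] = solvents.get(k, 0.0) + v
        impurities = dict(self.impurities)
        for k, v in other.impurities.items():
            impurities[k] = impurities.get(k, 0.0) + v
        return Stream(
            self.api_solid + other.api_solid,
            self.api_dissolved + other.api_dissolved,
            solvents,
            impurities,
        )


@dataclass(frozen=True)
class FeedSuspension:
    """Post-crystallization slurry: crystals suspended in mother liquor.

    Densities are in g/mL; dissolved solutes contribute to the mother
    liquor density with their own (crystal) densities under ideal mixing.
    """

    solid_api_mass: float  # g
    dissolved_api_mass: float  # g
    solvent_masses: dict[str, float]  # g per solvent
    dissolved_impurity_masses: dict[str, float] = field(default_factory=dict)
    crystal_density: float = 1.293  # g/mL (paracetamol default)
    solvent_densities: dict[str, float] = field(default_factory=dict)
    impurity_densities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.solid_api_mass <= 0:
            raise ValueError("solid_api_mass must be > 0 for isolation runs")
        if self.dissolved_api_mass < 0 or any(
            v < 0 for v in list(self.solvent_masses.values())
            + list(self.dissolved_impurity_masses.values())
        ):
            raise ValueError("masses must be non-negative")

    def to_stream(self) -> Stream:
        return Stream(
            api_solid=self.solid_api_mass,
            api_dissolved=self.dissolved_api_mass,
            solvents=dict(self.solvent_masses),
            impurities=dict(self.dissolved_impurity_masses),
        )

    def liquid_densities(self) -> dict[str, float]:
        """Density map over the flat liquid component keys."""
        out = {"api_dissolved": self.crystal_density}
        for k, rho in self.solvent_densities.items():
            out[f"solvent:{k}"] = rho
        for k in self.dissolved_impurity_masses:
            out[f"impurity:{k}"] = self.impurity_densities.get(k, self.crystal_density)
        return out

    def mother_liquor_density(self) -> float:
        """Mass-weighted mother liquor density in g/mL."""
        liquid = {
            "api_dissolved": self.dissolved_api_mass,
            **{f"solvent:{k}": v for k, v in self.solvent_masses.items()},
            **{f"impurity:{k}": v for k, v in self.dissolved_impurity_masses.items()},
        }
        return mixture_density(liquid, self.liquid_densities())


@dataclass(frozen=True)
class Wash:
    """One wash: amount in cake void volumes and solvent composition.

    ``composition`` holds mass fractions over solvents (sums to 1);
    ``dissolved`` optionally loads the wash with solutes, as mass
    fractions of the total tranche ('api' keys the dissolved API).
    """

    void_volumes: float
    composition: dict[str, float]
    n_steps: int = 10
    dissolved: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.void_volumes <= 0:
            raise ValueError("wash amount must be > 0 void volumes")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("wash composition mass fractions must sum to 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class WashSpec:
    washes: tuple[Wash, ...]

    def __post_init__(self) -> None:
        if not self.washes:
            raise ValueError("wash schedule is empty")


@dataclass
class Checkpoint:
    """State at a wash boundary (and optionally at interior steps)."""

    label: str
    cumulative_void_volumes: float
    ecv: float  # void volumes x porosity (the reporting convention)
    filtrate: Stream  # filtrate collected since the previous checkpoint
    removal: dict[str, float]  # cumulative % per impurity, vs feed
    washing_yield: float  # % of feed API retained in the cake


@dataclass
class IsolationResult:
    feed: Stream
    cake: Stream  # final cake (solids + residual liquid + any precipitate)
    filtration_filtrate: Stream
    filtration_yield: float  # % of feed API retained in cake after filtration
    checkpoints: list[Checkpoint]
    washing_yield: float  # % of feed API retained at the end of washing
    removal: dict[str, float]  # final cumulative % per impurity
    residual_impurities: dict[str, float]  # g left in the cake (incl. precipitate)
    flags: dict[str, int]  # flag -> 1-based step index at which it first fired
    precipitated: dict[str, float] = field(default_factory=dict)

    @property
    def wash_filtrates(self) -> list[Stream]:
        return [cp.filtrate for cp in self.checkpoints]
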