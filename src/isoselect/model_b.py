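"""Model B: constant-pressure cake filtration plus dispersion washing.

Filtration follows the classical constant-pressure Darcy form

    t(V) = mu * alpha * w * V^2 / (2 * A^2 * dP) + mu * R_m * V / (A * dP)

with specific cake resistance ``alpha`` (m/kg) either measured or
estimated from particle size via Kozeny-Carman, and medium resistance
``R_m`` (1/m).  Washing solves, per dissolved species, the 1-D
advection-dispersion equation on the cake height

    dc/dt = D_L * d2c/dz2 - v * dc/dz

with a Danckwerts-type advective inlet at the wash composition and a
free-outflow outlet at the filter medium, discretized with explicit
upwind advection and central dispersion under CFL control (a transparent
scheme that can be checked against the closed-form erfc transport
solution).  Dispersion gives the wash front a tail, so — unlike the
ideal-displacement model A — residual solute never reaches exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curves import BinaryCurve
from .model_a import (
    cake_void_volume,
    filtration_phase_split,
    impurity_removal_percent,
)
from .streams import (
    Checkpoint,
    FeedSuspension,
    IsolationResult,
    Stream,
    WashSpec,
    mixture_density,
)

__all__ = [
    "FiltrationSetup",
    "DispersionWashSetup",
    "FiltrationOutcome",
    "kozeny_carman_resistance",
    "constant_pressure_filtration",
    "advance_dispersion",
    "solve_transport",
    "dispersion_wash",
    "simulate_isolation_b",
]


def advance_dispersion(
    c: np.ndarray, c_in: float, v: float, d: float, dz: float, dt: float
) -> tuple[np.ndarray, float]:
    """One conservative explicit step of the advection-dispersion solver.

    Upwind advective and central dispersive face fluxes; the inlet face
    carries the advective wash flux only (Danckwerts closed inlet), the
    outlet face the advective outflow only.  Returns the updated cell
    concentrations and the outlet flux (mass per void cross-section per
    time).  Stability requires dt <= min(dz/v, dz^2/(2 d)) x CFL.
    """
    n = c.size
    flux = np.empty(n + 1)
    flux[0] = v * c_in
    flux[1:n] = v * c[:-1] - d * (c[1:] - c[:-1]) / dz
    flux[n] = v * c[-1]
    return c + dt / dz * (flux[:-1] - flux[1:]), float(flux[n])


def solve_transport(
    c0: np.ndarray,
    c_in: float,
    velocity: float,
    dispersion: float,
    cake_height: float,
    duration: float,
    cfl: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Integrate one species to ``duration``; returns (profile, removed).

    ``velocity`` is the interstitial velocity; ``removed`` is the
    effluent integral per unit void cross-section.
    """
    c = np.array(c0, dtype=float)
    dz = cake_height / c.size
    dt = cfl * min(dz / velocity, dz * dz / (2.0 * dispersion))
    removed = 0.0
    t = 0.0
    while t < duration - 1e-15:
        step = min(dt, duration - t)
        c, outflux = advance_dispersion(c, c_in, velocity, dispersion, dz, step)
        removed += outflux * step
        t += step
    return c, removed


def kozeny_carman_resistance(
    d50: float, sphericity: float, porosity: float, crystal_density: float
) -> float:
    """Specific cake resistance alpha = 180 (1-eps) / (rho_c phi^2 d^2 eps^3).

    d50 in m, crystal_density in kg/m^3 -> alpha in m/kg.  Strictly
    decreasing in particle size and porosity.
    """
    if min(d50, sphericity, crystal_density) <= 0 or not 0 < porosity < 1:
        raise ValueError("all inputs must be positive with porosity in (0, 1)")
    return (
        180.0
        * (1.0 - porosity)
        / (crystal_density * sphericity**2 * d50**2 * porosity**3)
    )


@dataclass(frozen=True)
class FiltrationSetup:
    """Constant-pressure filtration parameters (SI units)."""

    pressure_drop: float  # Pa
    filter_area: float  # m^2
    liquid_viscosity: float  # Pa.s
    specific_cake_resistance: float | None = None  # m/kg; Kozeny-Carman fallback
    medium_resistance: float = 1.0e6  # 1/m
    solids_mass_per_filtrate_volume: float | None = None  # kg/m^3; from feed if None
    porosity: float = 0.5
    particle_d50: float | None = None  # m
    sphericity: float = 1.0
    crystal_density: float = 1293.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.pressure_drop <= 0:
            raise ValueError("pressure drop must be > 0")
        if self.filter_area <= 0 or self.liquid_viscosity <= 0:
            raise ValueError("filter area and viscosity must be > 0")
        if not 0 < self.porosity < 1:
            raise ValueError("porosity must lie in (0, 1)")

    def resistance(self) -> float:
        if self.specific_cake_resistance is not None:
            return self.specific_cake_resistance
        if self.particle_d50 is None:
            raise ValueError("need specific_cake_resistance or particle_d50")
        return kozeny_carman_resistance(
            self.particle_d50, self.sphericity, self.porosity, self.crystal_density
        )


@dataclass
class FiltrationOutcome:
    time: float  # s to the target volume
    volumes: np.ndarray  # m^3
    times: np.ndarray  # s
    flow_rates: np.ndarray  # m^3/s
    filtrate: Stream | None = None
    wet_cake: Stream | None = None


def constant_pressure_filtration(
    setup: FiltrationSetup,
    target_volume: float,
    feed: FeedSuspension | None = None,
    n_points: int = 200,
) -> FiltrationOutcome:
    """Closed-form constant-pressure filtration to ``target_volume`` (m^3).

    When a feed is supplied, the dissolved-species phase split of the
    ideal dryland model is attached (identical contract to model A).
    """
    if target_volume <= 0:
        raise ValueError("target volume must be > 0")
    alpha = setup.resistance()
    mu, a, dp, rm = (
        setup.liquid_viscosity,
        setup.filter_area,
        setup.pressure_drop,
        setup.medium_resistance,
    )
    filtrate = wet_cake = None
    if feed is not None:
        w = setup.solids_mass_per_filtrate_volume
        if w is None:
            liquid_mass = feed.to_stream().total_mass - feed.solid_api_mass
            cake_liquid = cake_void_volume(feed, setup.porosity) * feed.mother_liquor_density()
            filtrate_volume = (liquid_mass - cake_liquid) / feed.mother_liquor_density() * 1e-6
            w = feed.solid_api_mass * 1e-3 / filtrate_volume
        wet_cake, filtrate = filtration_phase_split(feed, setup.porosity)
    else:
        w = setup.solids_mass_per_filtrate_volume
        if w is None:
            raise ValueError("need solids_mass_per_filtrate_volume or a feed")
    volumes = np.linspace(0.0, target_volume, n_points)
    times = mu * alpha * w * volumes**2 / (2 * a**2 * dp) + mu * rm * volumes / (a * dp)
    with np.errstate(divide="ignore"):  # rm = 0 gives an infinite initial rate
        flow_rates = a**2 * dp / (mu * (alpha * w * volumes + rm * a))
    return FiltrationOutcome(
        time=float(times[-1]),
        volumes=volumes,
        times=times,
        flow_rates=flow_rates,
        filtrate=filtrate,
        wet_cake=wet_cake,
    )


@dataclass(frozen=True)
class DispersionWashSetup:
    """Advection-dispersion washing parameters."""

    washes: WashSpec
    axial_dispersion_coefficient: float = 1.0e-9  # m^2/s
    cake_height: float = 0.05  # m
    superficial_velocity: float = 1.0e-4  # m/s
    n_cells: int = 200
    cfl: float = 0.5
    strict_paper: bool = False  # disable gradient-solubility risk flags

    def __post_init__(self) -> None:
        if self.axial_dispersion_coefficient <= 0:
            raise ValueError("dispersion coefficient must be > 0")
        if self.n_cells < 10:
            raise ValueError("need at least 10 grid cells")
        if not 0 < self.cfl <= 0.5:
            raise ValueError("CFL number must lie in (0, 0.5]")
        if self.cake_height <= 0 or self.superficial_velocity <= 0:
            raise ValueError("cake height and velocity must be > 0")


def dispersion_wash(
    setup: DispersionWashSetup,
    cake: Stream,
    feed: FeedSuspension,
    porosity: float,
    cryst_solvent: str,
    curves: dict[str, BinaryCurve] | None = None,
    filtration_filtrate: Stream | None = None,
) -> IsolationResult:
    """Wash the saturated cake by 1-D advection-dispersion transport.

    Every liquid component (each solvent, dissolved API, each impurity)
    is a transported scalar with uniform initial concentration in the
    voids and the wash composition at the inlet; the effluent integrates
    into per-wash filtrate streams.  Risk flags are evaluated per step
    from the cake-average composition on the binary curves (advisory
    only; no precipitation mass transfer), unless ``strict_paper`` mode
    disables the gradient-solubility coupling.
    """
    liq = {k: v for k, v in cake.component_masses().items() if k != "api_solid"}
    liquid_mass = sum(liq.values())
    if liquid_mass <= 0:
        raise ValueError("cake carries no liquid phase")
    curves = curves or {}
    feed_stream = feed.to_stream()
    densities = feed.liquid_densities()
    for solute in curves:
        key = "api_dissolved" if solute == "api" else f"impurity:{solute}"
        if key not in liq and solute != "api":
            raise KeyError(f"curve provided for unknown solute {solute!r}")

    n = setup.n_cells
    h = setup.cake_height
    dz = h / n
    v = setup.superficial_velocity / porosity  # interstitial velocity
    d = setup.axial_dispersion_coefficient
    void_volume_m3 = cake_void_volume(feed, porosity) * 1e-6
    cell_volume = void_volume_m3 / n

    keys = set(liq)
    for wash in setup.washes.washes:
        keys.update(f"solvent:{k}" for k in wash.composition)
        keys.update(
            "api_dissolved" if k == "api" else f"impurity:{k}" for k in wash.dissolved
        )
    species = sorted(keys)
    conc = {
        k: np.full(n, liq.get(k, 0.0) / void_volume_m3) for k in species
    }  # g/m^3 voids
    dissolved_api_ref = liq.get("api_dissolved", 0.0)
    flags: dict[str, int] = {}
    checkpoints: list[Checkpoint] = []
    cumulative_vv = 0.0
    step_index = 0

    dt = setup.cfl * min(dz / v, dz * dz / (2.0 * d))
    area_void = void_volume_m3 / h  # effective void cross-section

    for w_idx, wash in enumerate(setup.washes.washes, start=1):
        for name in wash.composition:
            if f"solvent:{name}" not in densities:
                raise KeyError(f"wash composition references unknown solvent {name!r}")
        rho_wash = mixture_density(
            {f"solvent:{k}": f for k, f in wash.composition.items()},
            densities,
        )
        solvent_part = 1.0 - sum(wash.dissolved.values())
        c_in = {k: 0.0 for k in species}
        for k, f in wash.composition.items():
            c_in[f"solvent:{k}"] = f * solvent_part * rho_wash * 1e6  # g/m^3
        for k, f in wash.dissolved.items():
            key = "api_dissolved" if k == "api" else f"impurity:{k}"
            c_in[key] = c_in.get(key, 0.0) + f * rho_wash * 1e6
        wash_time = wash.void_volumes * h / v  # time to pump the wash volume
        removed: dict[str, float] = {k: 0.0 for k in species}
        t_done = 0.0
        while t_done < wash_time - 1e-15:
            step = min(dt, wash_time - t_done)
            step_index += 1
            for k in species:
                conc[k], outflux = advance_dispersion(
                    conc[k], c_in[k], v, d, dz, step
                )
                removed[k] += outflux * area_void * step
            t_done += step
            if curves and not setup.strict_paper:
                avg = {k: float(np.mean(conc[k])) * void_volume_m3 for k in species}
                solvent_mass = sum(
                    m for k, m in avg.items() if k.startswith("solvent:")
                )
                if solvent_mass > 0:
                    f = 1.0 - avg.get(f"solvent:{cryst_solvent}", 0.0) / solvent_mass
                    f = min(1.0, max(0.0, f))
                    for solute, curve in curves.items():
                        cap = curve(f) * solvent_mass / 100.0
                        if solute == "api":
                            if cap > dissolved_api_ref * (1 + 1e-9) + 1e-12:
                                flags.setdefault("API_DISSOLUTION_RISK", step_index)
                        elif avg.get(f"impurity:{solute}", 0.0) > cap * (1 + 1e-9) + 1e-12:
                            flags.setdefault(
                                f"IMPURITY_PRECIPITATION_RISK:{solute}", step_index
                            )
        cumulative_vv += wash.void_volumes
        residual = {k: float(np.sum(conc[k])) * cell_volume for k in species}
        removal = {
            name: impurity_removal_percent(
                feed_stream.impurities[name], residual.get(f"impurity:{name}", 0.0)
            )
            if feed_stream.impurities.get(name, 0.0) > 0
            else math.nan
            for name in feed_stream.impurities
        }
        washing_yield = 100.0 * (
            cake.api_solid + residual.get("api_dissolved", 0.0)
        ) / feed_stream.api_mass
        checkpoints.append(
            Checkpoint(
                label=f"wash {w_idx}",
                cumulative_void_volumes=cumulative_vv,
                ecv=cumulative_vv * porosity,
                filtrate=_flat_to_stream(removed),
                removal=removal,
                washing_yield=washing_yield,
            )
        )

    residual = {k: float(np.sum(conc[k])) * cell_volume for k in species}
    final_cake = _flat_to_stream(residual)
    final_cake.api_solid = cake.api_solid
    return IsolationResult(
        feed=feed_stream,
        cake=final_cake,
        filtration_filtrate=filtration_filtrate
        if filtration_filtrate is not None
        else Stream(),
        filtration_yield=100.0 * cake.api_mass / feed_stream.api_mass,
        checkpoints=checkpoints,
        washing_yield=checkpoints[-1].washing_yield,
        removal=checkpoints[-1].removal,
        residual_impurities={
            name: residual.get(f"impurity:{name}", 0.0)
            for name in feed_stream.impurities
        },
        flags=flags,
    )


def _flat_to_stream(flat: dict[str, float]) -> Stream:
    return Stream(
        api_solid=flat.get("api_solid", 0.0),
        api_dissolved=max(flat.get("api_dissolved", 0.0), 0.0),
        solvents={
            k.split(":", 1)[1]: max(v, 0.0)
            for k, v in flat.items()
            if k.startswith("solvent:")
        },
        impurities={
            k.split(":", 1)[1]: max(v, 0.0)
            for k, v in flat.items()
            if k.startswith("impurity:")
        },
    )


def simulate_isolation_b(
    feed: FeedSuspension,
    filtration: FiltrationSetup,
    wash_setup: DispersionWashSetup,
    cryst_solvent: str,
    curves: dict[str, BinaryCurve] | None = None,
) -> tuple[IsolationResult, FiltrationOutcome]:
    """Chain dryland phase split, Darcy filtration timing, dispersion wash.

    The wash superficial velocity is derived from the Darcy flow at the
    end of cake formation (washing at the filtration pressure through
    the fully formed cake), overriding the setup default.
    """
    liquid_mass = feed.to_stream().total_mass - feed.solid_api_mass
    rho_ml = feed.mother_liquor_density()
    cake_liquid = cake_void_volume(feed, filtration.porosity) * rho_ml
    target_volume = (liquid_mass - cake_liquid) / rho_ml * 1e-6  # m^3 to dryland
    outcome = constant_pressure_filtration(filtration, target_volume, feed)
    u_wash = float(outcome.flow_rates[-1]) / filtration.filter_area
    cake_volume_m3 = feed.solid_api_mass * 1e-3 / filtration.crystal_density / (
        1.0 - filtration.porosity
    )
    height = cake_volume_m3 / filtration.filter_area
    wash = DispersionWashSetup(
        washes=wash_setup.washes,
        axial_dispersion_coefficient=wash_setup.axial_dispersion_coefficient,
        cake_height=height,
        superficial_velocity=u_wash,
        n_cells=wash_setup.n_cells,
        cfl=wash_setup.cfl,
        strict_paper=wash_setup.strict_paper,
    )
    result = dispersion_wash(
        wash,
        outcome.wet_cake,
        feed,
        filtration.porosity,
        cryst_solvent,
        curves=curves,
        filtration_filtrate=outcome.filtrate,
    )
    return result, outcome
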