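"""Model A: ideal-displacement isolation simulator (workflow stages 8-9).

Filtration is a pure phase split: the cake keeps all crystals plus
enough mother liquor to saturate its voids (dryland endpoint), the rest
leaves as filtrate at the mother-liquor composition.  Washing is ideal
plug displacement, discretized into tranches (10 per wash by default):
each tranche of wash pushes an equal mass of the *original* residual
mother liquor out to the filtrate at its undiluted composition until
that liquor is exhausted, and only then displaces the current (mixed)
cake liquid; meanwhile the tranche mixes fully into the cake voids, and
the mixed composition — located on the binary solubility curves — drives
the API-dissolution and impurity-precipitation risk flags.  The flags
carry no kinetics: solubility caps are compared and risks reported; an
optional worst-case mode converts super-solubility impurity into
unwashable solid retained in the cake.
"""

from __future__ import annotations

import math

from .curves import BinaryCurve
from .streams import (
    Checkpoint,
    FeedSuspension,
    IsolationResult,
    Stream,
    Wash,
    WashSpec,
    mixture_density,
)

__all__ = [
    "feed_mass_fractions",
    "cake_void_volume",
    "filtration_phase_split",
    "displacement_wash",
    "impurity_removal_percent",
    "simulate_isolation_a",
]

_EPS = 1e-12


def feed_mass_fractions(feed: FeedSuspension) -> Stream:
    """The feed as a stream; fractions via ``.mass_fractions()`` etc.

    The API fraction counts solid plus dissolved API over the total
    suspension mass.
    """
    stream = feed.to_stream()
    if stream.total_mass <= 0:
        raise ValueError("feed has zero total mass")
    return stream


def cake_void_volume(feed: FeedSuspension, porosity: float) -> float:
    """Cake void volume in mL: (solids volume) * porosity / (1 - porosity)."""
    if not 0 < porosity < 1:
        raise ValueError("porosity must lie in (0, 1)")
    solids_volume = feed.solid_api_mass / feed.crystal_density
    return solids_volume * porosity / (1.0 - porosity)


def filtration_phase_split(
    feed: FeedSuspension,
    porosity: float,
    endpoint: str = "dryland",
    residual_saturation: float = 1.0,
) -> tuple[Stream, Stream]:
    """Split the feed into a liquid-saturated cake and a filtrate.

    The cake holds all solid API plus ``void_volume * S * rho_ML`` grams
    of mother liquor (saturation S = 1 at dryland; the user-set residual
    saturation < 1 at breakthrough).  Cake and filtrate liquids share the
    mother-liquor mass fractions; every species is conserved.
    """
    if endpoint not in ("dryland", "breakthrough"):
        raise ValueError(f"unknown filtration endpoint {endpoint!r}")
    if endpoint == "dryland":
        saturation = 1.0
    else:
        if not 0 < residual_saturation <= 1:
            raise ValueError("residual_saturation must lie in (0, 1]")
        saturation = residual_saturation
    void_volume = cake_void_volume(feed, porosity)
    rho_ml = feed.mother_liquor_density()
    cake_liquid_mass = void_volume * saturation * rho_ml
    liquor = feed.to_stream()
    liquid_mass = liquor.total_mass - feed.solid_api_mass
    if cake_liquid_mass > liquid_mass * (1 + 1e-9):
        raise ValueError(
            "infeasible split: cake voids demand "
            f"{cake_liquid_mass:.3f} g of liquor but only {liquid_mass:.3f} g available"
        )
    keep = cake_liquid_mass / liquid_mass
    cake = Stream(
        api_solid=feed.solid_api_mass,
        api_dissolved=feed.dissolved_api_mass * keep,
        solvents={k: v * keep for k, v in feed.solvent_masses.items()},
        impurities={k: v * keep for k, v in feed.dissolved_impurity_masses.items()},
    )
    filtrate = Stream(
        api_solid=0.0,
        api_dissolved=feed.dissolved_api_mass * (1 - keep),
        solvents={k: v * (1 - keep) for k, v in feed.solvent_masses.items()},
        impurities={k: v * (1 - keep) for k, v in feed.dissolved_impurity_masses.items()},
    )
    return cake, filtrate


def impurity_removal_percent(feed_impurity: float, residual_impurity: float) -> float:
    """Percentage of the feed impurity mass no longer in the cake."""
    if feed_impurity <= 0:
        raise ValueError("feed impurity mass must be > 0")
    if residual_impurity > feed_impurity * (1 + 1e-9):
        raise ValueError("residual impurity exceeds feed: conservation breach upstream")
    return 100.0 * (feed_impurity - min(residual_impurity, feed_impurity)) / feed_impurity


def _wash_density(wash: Wash, feed: FeedSuspension) -> float:
    masses = {f"solvent:{k}": v for k, v in wash.composition.items()}
    solvent_part = 1.0 - sum(wash.dissolved.values())
    masses = {k: v * solvent_part for k, v in masses.items()}
    densities = dict(feed.liquid_densities())
    for k, v in wash.dissolved.items():
        key = "api_dissolved" if k == "api" else f"impurity:{k}"
        masses[key] = masses.get(key, 0.0) + v
        densities.setdefault(key, feed.crystal_density)
    for k in wash.composition:
        if f"solvent:{k}" not in densities:
            raise KeyError(f"wash composition references unknown solvent {k!r}")
    return mixture_density(masses, densities)


def _wash_fraction(liq: dict[str, float], cryst_solvent: str) -> float:
    """Wash-solvent mass fraction of the solvent part of the cake liquid."""
    solvent_mass = sum(v for k, v in liq.items() if k.startswith("solvent:"))
    if solvent_mass <= 0:
        return 1.0
    cryst = liq.get(f"solvent:{cryst_solvent}", 0.0)
    return min(1.0, max(0.0, 1.0 - cryst / solvent_mass))


def _stream_from_flat(flat: dict[str, float]) -> Stream:
    return Stream(
        api_solid=flat.get("api_solid", 0.0),
        api_dissolved=flat.get("api_dissolved", 0.0),
        solvents={
            k.split(":", 1)[1]: v for k, v in flat.items() if k.startswith("solvent:")
        },
        impurities={
            k.split(":", 1)[1]: v for k, v in flat.items() if k.startswith("impurity:")
        },
    )


def displacement_wash(
    cake: Stream,
    spec: WashSpec,
    curves: dict[str, BinaryCurve],
    feed: FeedSuspension,
    porosity: float,
    cryst_solvent: str,
    filtration_filtrate: Stream | None = None,
    precipitation: str = "flag",
) -> IsolationResult:
    """Run the discretized ideal-displacement wash on a saturated cake.

    ``curves`` maps solute names ('api' for the API, impurity names
    otherwise) to binary solubility curves along the crystallization->
    wash gradient; solubility caps are evaluated on a g per 100 g
    *solvent* basis at the post-mixing cake composition.

    ``precipitation`` selects how a super-solubility impurity is
    handled: ``"flag"`` (default) raises the risk flag and leaves the
    mass balance untouched — no kinetics are modelled; ``"retain"``
    additionally converts the excess to unwashable solid retained in the
    cake, a worst-case purity bound.
    """
    if precipitation not in ("flag", "retain"):
        raise ValueError(f"unknown precipitation mode {precipitation!r}")
    if cake.total_mass - cake.api_solid <= 0:
        raise ValueError("cake carries no liquid phase")
    void_volume = cake_void_volume(feed, porosity)
    feed_stream = feed.to_stream()

    liq = {k: v for k, v in cake.component_masses().items() if k != "api_solid"}
    liquor_mass = sum(liq.values())
    frac0 = {k: v / liquor_mass for k, v in liq.items()}
    remaining_original = liquor_mass
    dissolved_api_ref = liq.get("api_dissolved", 0.0)
    precipitated = {name: 0.0 for name in cake.impurities}
    flags: dict[str, int] = {}
    checkpoints: list[Checkpoint] = []
    cumulative_vv = 0.0
    step_index = 0

    for solute in list(curves):
        key = "api_dissolved" if solute == "api" else f"impurity:{solute}"
        if key not in liq and solute != "api":
            raise KeyError(f"curve provided for unknown solute {solute!r}")

    for w_idx, wash in enumerate(spec.washes, start=1):
        for name in wash.composition:
            if name not in feed.solvent_densities:
                raise KeyError(f"wash composition references unknown solvent {name!r}")
        wash_mass = wash.void_volumes * void_volume * _wash_density(wash, feed)
        dm = wash_mass / wash.n_steps
        solvent_part = 1.0 - sum(wash.dissolved.values())
        tranche = {
            f"solvent:{k}": dm * solvent_part * v for k, v in wash.composition.items()
        }
        for k, v in wash.dissolved.items():
            key = "api_dissolved" if k == "api" else f"impurity:{k}"
            tranche[key] = tranche.get(key, 0.0) + dm * v
        filtrate_acc: dict[str, float] = {}
        for _ in range(wash.n_steps):
            step_index += 1
            # (i) plug displacement to the filtrate at the pre-mixing composition
            expel_orig = min(dm, remaining_original)
            expel_mix = dm - expel_orig
            removed: dict[str, float] = {}
            for k in liq:
                amount = frac0.get(k, 0.0) * expel_orig
                removed[k] = min(amount, liq[k])
            if expel_mix > 0:
                pool = sum(liq.values()) - sum(removed.values())
                if pool > 0:
                    scale = expel_mix / pool
                    for k in liq:
                        removed[k] = removed[k] + (liq[k] - removed[k]) * scale
            for k, v in removed.items():
                liq[k] -= v
                filtrate_acc[k] = filtrate_acc.get(k, 0.0) + v
            remaining_original -= expel_orig
            # (ii) the tranche mixes fully with the remaining cake liquid
            for k, v in tranche.items():
                liq[k] = liq.get(k, 0.0) + v
            # (iii) risk flags from solubilities at the new composition
            f = _wash_fraction(liq, cryst_solvent)
            solvent_mass = sum(v for k, v in liq.items() if k.startswith("solvent:"))
            for solute, curve in curves.items():
                cap = curve(f) * solvent_mass / 100.0
                if solute == "api":
                    if cap > dissolved_api_ref * (1 + 1e-9) + _EPS:
                        flags.setdefault("API_DISSOLUTION_RISK", step_index)
                else:
                    key = f"impurity:{solute}"
                    dissolved = liq.get(key, 0.0)
                    if dissolved > cap * (1 + 1e-9) + _EPS:
                        flags.setdefault(
                            f"IMPURITY_PRECIPITATION_RISK:{solute}", step_index
                        )
                        if precipitation == "retain":
                            precipitated[solute] = (
                                precipitated.get(solute, 0.0) + dissolved - cap
                            )
                            liq[key] = cap
            cumulative_vv += wash.void_volumes / wash.n_steps
        removal = {
            name: impurity_removal_percent(
                feed_stream.impurities[name],
                liq.get(f"impurity:{name}", 0.0) + precipitated.get(name, 0.0),
            )
            if feed_stream.impurities[name] > 0
            else math.nan
            for name in feed_stream.impurities
        }
        washing_yield = 100.0 * (
            cake.api_solid + liq.get("api_dissolved", 0.0)
        ) / feed_stream.api_mass
        checkpoints.append(
            Checkpoint(
                label=f"wash {w_idx}",
                cumulative_void_volumes=cumulative_vv,
                ecv=cumulative_vv * porosity,
                filtrate=_stream_from_flat(filtrate_acc),
                removal=removal,
                washing_yield=washing_yield,
            )
        )

    final_cake = _stream_from_flat(liq)
    final_cake.api_solid = cake.api_solid
    for name, mass in precipitated.items():
        final_cake.impurities[name] = final_cake.impurities.get(name, 0.0) + mass
    filtration_yield = 100.0 * cake.api_mass / feed_stream.api_mass
    return IsolationResult(
        feed=feed_stream,
        cake=final_cake,
        filtration_filtrate=filtration_filtrate
        if filtration_filtrate is not None
        else Stream(),
        filtration_yield=filtration_yield,
        checkpoints=checkpoints,
        washing_yield=checkpoints[-1].washing_yield,
        removal=checkpoints[-1].removal,
        residual_impurities={
            name: liq.get(f"impurity:{name}", 0.0) + precipitated.get(name, 0.0)
            for name in feed_stream.impurities
        },
        flags=flags,
        precipitated=precipitated,
    )


def simulate_isolation_a(
    feed: FeedSuspension,
    porosity: float,
    spec: WashSpec,
    curves: dict[str, BinaryCurve],
    cryst_solvent: str,
    endpoint: str = "dryland",
    residual_saturation: float = 1.0,
    precipitation: str = "flag",
) -> IsolationResult:
    """Chain the dryland/breakthrough phase split and the displacement wash."""
    cake, filtrate = filtration_phase_split(feed, porosity, endpoint, residual_saturation)
    return displacement_wash(
        cake, spec, curves, feed, porosity, cryst_solvent,
        filtration_filtrate=filtrate, precipitation=precipitation,
    )
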