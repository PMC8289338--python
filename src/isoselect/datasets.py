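"""Bundled reference data for the paracetamol isolation case study.

Curated, programmatically constructed tables for the solvents appearing
in the paracetamol / acetanilide / metacetamol purification case study:
a small solvent-property table (literature-typical ambient values), the
published pure-solvent solubilities of the three solutes, back-solved
crystallization loadings, and the three validation experiments (Exp1:
ethanol -> n-heptane; Exp2: 2-propanol -> n-heptane; Exp3:
3-methyl-1-butanol -> n-dodecane) with their feed masses, cake
properties and wash schedules.

Impurity solubilities in the pure *crystallization* solvents are not
published; the values bundled here are synthetic plausible estimates
(both impurities dissolve freely in the alcohols) and are labelled as
such.  They position the binary-curve endpoints for risk flagging only
and do not enter the displacement mass balance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crystallization import CrystallizationCandidate
from .curves import BinaryCurve, build_binary_curve
from .model_b import DispersionWashSetup, FiltrationSetup
from .solvents import Solvent, SolubilityTable, SolventTable
from .streams import FeedSuspension, Wash, WashSpec

__all__ = [
    "case_study_solvents",
    "case_study_solubilities",
    "crystallization_candidates",
    "Experiment",
    "experiment",
    "EXPERIMENT_NAMES",
]

API = "paracetamol"
IMPURITIES = ("acetanilide", "metacetamol")

# density g/mL, viscosity Pa.s, mp/bp degC, vapor pressure Pa, dHvap kJ/mol,
# ICH class (None = unlisted), six GSK scores.  Ambient literature-typical
# values, curated for the case-study solvents.
_SOLVENTS = [
    # name, rho, mu, mp, bp, vp, dhvap, ich, (waste, env, health, flam, react, lc)
    ("ethanol", 0.789, 1.20e-3, -114.1, 78.2, 5870.0, 42.3, 3, (7, 8, 8, 6, 9, 8)),
    ("2-propanol", 0.785, 2.04e-3, -89.0, 82.4, 4400.0, 44.0, 3, (7, 8, 8, 6, 9, 8)),
    ("n-heptane", 0.684, 4.1e-4, -90.6, 98.4, 5330.0, 36.6, 3, (6, 3, 7, 4, 9, 7)),
    ("n-dodecane", 0.750, 1.34e-3, -9.6, 216.2, 18.0, 61.5, None, (6, 3, 7, 7, 9, 7)),
    ("3-methyl-1-butanol", 0.810, 3.7e-3, -117.2, 131.1, 315.0, 55.4, 3, (7, 7, 7, 7, 9, 7)),
    ("isopropyl acetate", 0.870, 5.2e-4, -73.4, 88.6, 8100.0, 37.2, 3, (7, 7, 8, 5, 8, 7)),
    ("2-pentanol", 0.810, 3.5e-3, -73.0, 119.3, 800.0, 54.0, None, (7, 7, 7, 6, 8, 7)),
    ("tert-butyl acetate", 0.866, 6.0e-4, -62.0, 97.8, 5300.0, 36.0, None, (7, 7, 7, 5, 8, 7)),
    ("1-octanol", 0.824, 7.6e-3, -14.8, 195.1, 10.0, 70.9, None, (6, 7, 7, 8, 8, 7)),
    ("butyl acetate", 0.882, 6.85e-4, -78.0, 126.1, 1500.0, 43.9, 3, (7, 7, 8, 6, 8, 7)),
    ("water", 0.997, 8.9e-4, 0.0, 100.0, 2300.0, 40.65, 3, (8, 10, 10, 10, 9, 10)),
    ("methanol", 0.792, 5.4e-4, -97.6, 64.7, 13000.0, 35.2, 2, (7, 8, 6, 6, 9, 8)),
    ("acetone", 0.784, 3.1e-4, -94.7, 56.1, 30800.0, 31.3, 3, (6, 7, 8, 4, 9, 8)),
    ("dichloromethane", 1.327, 4.1e-4, -96.7, 39.6, 58000.0, 28.8, 2, (5, 3, 5, 10, 9, 7)),
    ("methyl isopropyl ketone", 0.803, 4.7e-4, -92.0, 94.5, 6700.0, 36.7, None, (7, 6, 7, 5, 8, 7)),
    ("propionic acid", 0.988, 1.03e-3, -20.7, 141.1, 470.0, 54.8, None, (6, 7, 5, 8, 8, 7)),
]

_GSK_KEYS = ("waste", "environment", "health", "flammability", "reactivity", "life_cycle")


def case_study_solvents() -> SolventTable:
    """Curated solvent-property table for the case-study solvents."""
    solvents = [
        Solvent(
            name=name,
            density=rho,
            viscosity=mu,
            melting_point=mp,
            boiling_point=bp,
            vapor_pressure=vp,
            enthalpy_vaporization=dh,
            ich_class=ich,
            gsk_scores=dict(zip(_GSK_KEYS, gsk)),
        )
        for name, rho, mu, mp, bp, vp, dh, ich, gsk in _SOLVENTS
    ]
    return SolventTable(solvents, provenance="curated case-study subset")


# Pure-solvent solubilities at 22 degC, g solute / 100 g solvent.
# Published values for the wash solvents and for paracetamol in the
# crystallization solvents ("<0.005" entries stored at the 0.005 bound).
_SOLUBILITY_PUBLISHED = {
    # wash solvent: (paracetamol, metacetamol, acetanilide)
    "n-heptane": (0.005, 0.005, 0.04),
    "isopropyl acetate": (2.73, 6.31, 11.20),
    "2-pentanol": (2.35, 3.60, 8.73),
    "tert-butyl acetate": (2.56, 6.11, 9.20),
    "1-octanol": (1.65, 2.54, 6.68),
    "methyl isopropyl ketone": (6.89, 14.91, 17.89),
    "propionic acid": (5.20, 6.55, 42.73),
    "n-dodecane": (0.005, 0.005, 0.03),
}

# paracetamol solubility in the crystallization solvents, g/g -> g/100 g
_PARACETAMOL_CRYST = {
    "ethanol": 15.44,
    "2-propanol": 5.86,
    "3-methyl-1-butanol": 4.82,
    "water": 0.88,
    "butyl acetate": 1.04,
    "methanol": 23.0,  # synthetic plausible (freely soluble)
}

# SYNTHETIC plausible impurity solubilities in the crystallization
# solvents (unpublished); flag-positioning only.
_IMPURITY_CRYST_SYNTHETIC = {
    # solvent: (metacetamol, acetanilide)
    "ethanol": (30.0, 25.0),
    "2-propanol": (22.0, 18.0),
    "3-methyl-1-butanol": (15.0, 12.0),
}


def case_study_solubilities() -> SolubilityTable:
    """Pure-solvent solubility table (22 degC) for the three solutes."""
    records = []
    for solvent, (para, met, acet) in _SOLUBILITY_PUBLISHED.items():
        records += [
            (API, solvent, 22.0, para),
            ("metacetamol", solvent, 22.0, met),
            ("acetanilide", solvent, 22.0, acet),
        ]
    for solvent, para in _PARACETAMOL_CRYST.items():
        records.append((API, solvent, 22.0, para))
    for solvent, (met, acet) in _IMPURITY_CRYST_SYNTHETIC.items():
        records += [
            ("metacetamol", solvent, 22.0, met),
            ("acetanilide", solvent, 22.0, acet),
        ]
    return SolubilityTable(records)


# Crystallization ranking data: cold solubility at 22 degC (g/g) with the
# hot loading back-solved from the published returned mass on a 100 g
# solvent basis (hot = cold + return/100); the dissolution-temperature
# loadings themselves are not published.
_CRYSTALLIZATION = {
    # name: (cold g/g, return g per 100 g solvent)
    "acetyl acetate": (0.0060, 36.13),
    "3-pentanone": (0.0100, 35.56),
    "butyl acetate": (0.0104, 34.48),
    "water": (0.0088, 17.57),
    "2-pentanol": (0.0235, 44.03),
    "dimethyl carbonate": (0.0134, 23.41),
    "methyl isobutyl ketone": (0.0342, 57.99),
    "propionic acid": (0.0520, 70.41),
    "formamide": (0.1017, 127.84),
    "2-pentanone": (0.0468, 56.60),
    "3-methyl-1-butanol": (0.0482, 51.65),
    "2-propanol": (0.0586, 29.39),
    "ethanol": (0.1544, 41.03),
}


def crystallization_candidates(solvent_mass: float = 100.0) -> list[CrystallizationCandidate]:
    """Case-study crystallization candidates on a 100 g solvent basis."""
    table = case_study_solvents()
    out = []
    for name, (cold, return_g) in _CRYSTALLIZATION.items():
        hot = cold + return_g / 100.0
        solvent = table.get(name) if name in table else Solvent(name=name)
        out.append(
            CrystallizationCandidate(
                solvent=solvent, hot_loading=hot, cold_solubility=cold,
                solvent_mass=solvent_mass,
            )
        )
    return out


_SOLVENT_DENSITIES = {
    "ethanol": 0.789,
    "2-propanol": 0.785,
    "n-heptane": 0.684,
    "3-methyl-1-butanol": 0.810,
    "n-dodecane": 0.750,
}
_IMPURITY_DENSITIES = {"acetanilide": 1.219, "metacetamol": 1.293}
PARACETAMOL_CRYSTAL_DENSITY = 1.293  # g/mL


@dataclass(frozen=True)
class Experiment:
    """One validation experiment: feed, cake and wash-schedule parameters."""

    name: str
    cryst_solvent: str
    wash_solvent: str
    feed: FeedSuspension
    porosity: float
    pressure_drop: float  # Pa
    cake_resistance: float  # m/kg
    particle_d50: float  # m
    void_volumes_per_wash: float
    n_washes: int
    wash1_cryst_fraction: float  # crystallization-solvent mass fraction of wash 1

    def wash_spec(self, n_steps: int = 10) -> WashSpec:
        """Wash 1 is a crystallization/wash solvent mixture (anti-solvent
        protection); subsequent washes are pure wash solvent."""
        first = Wash(
            void_volumes=self.void_volumes_per_wash,
            composition={
                self.cryst_solvent: self.wash1_cryst_fraction,
                self.wash_solvent: 1.0 - self.wash1_cryst_fraction,
            },
            n_steps=n_steps,
        )
        rest = [
            Wash(
                void_volumes=self.void_volumes_per_wash,
                composition={self.wash_solvent: 1.0},
                n_steps=n_steps,
            )
            for _ in range(self.n_washes - 1)
        ]
        return WashSpec((first, *rest))

    def curves(self) -> dict[str, BinaryCurve]:
        """Two-knot log-linear binary curves anchored at the pure-solvent
        solubilities ('api' plus each impurity)."""
        table = case_study_solubilities()
        out: dict[str, BinaryCurve] = {}
        for solute, key in [(API, "api"), *[(i, i) for i in IMPURITIES]]:
            s0 = table.get(solute, self.cryst_solvent, 22.0)
            s1 = table.get(solute, self.wash_solvent, 22.0)
            out[key] = build_binary_curve(
                [(0.0, s0), (1.0, s1)],
                interpolation="log_linear",
                solute=solute,
                cryst_solvent=self.cryst_solvent,
                wash_solvent=self.wash_solvent,
            )
        return out

    def filtration_setup(self, filter_area: float = 3.1416e-4) -> FiltrationSetup:
        """Darcy filtration parameters; the default area is a placeholder
        cylindrical-port geometry (20 mm diameter), configurable."""
        table = case_study_solvents()
        return FiltrationSetup(
            pressure_drop=self.pressure_drop,
            filter_area=filter_area,
            liquid_viscosity=table.get(self.cryst_solvent).viscosity,
            specific_cake_resistance=self.cake_resistance,
            medium_resistance=1.0e6,
            porosity=self.porosity,
            particle_d50=self.particle_d50,
            sphericity=1.0,
            crystal_density=PARACETAMOL_CRYSTAL_DENSITY * 1000.0,
        )

    def dispersion_setup(
        self, n_steps: int = 10, dispersion: float = 1.0e-9, n_cells: int = 200
    ) -> DispersionWashSetup:
        return DispersionWashSetup(
            washes=self.wash_spec(n_steps=n_steps),
            axial_dispersion_coefficient=dispersion,
            n_cells=n_cells,
        )


_EXPERIMENTS = {
    # name: (cryst, wash, solid g, solvent g, dissolved API g, acetanilide g,
    #        metacetamol g, porosity, alpha m/kg, d50 um, vv/wash, wash1 cryst frac)
    "exp1": ("ethanol", "n-heptane", 14.202, 94.68, 13.681, 0.499, 0.558,
             0.46, 6.3e8, 13.85, 4.0, 0.5),
    "exp2": ("2-propanol", "n-heptane", 16.506, 110.04, 8.932, 0.455, 0.509,
             0.44, 5.9e7, 77.36, 2.0, 0.5),
    "exp3": ("3-methyl-1-butanol", "n-dodecane", 24.3, 97.2, 4.921, 0.522, 0.584,
             0.44, 5.63e8, 77.36, 2.0, 0.2),
}

EXPERIMENT_NAMES = tuple(_EXPERIMENTS)


def experiment(name: str) -> Experiment:
    """The validation experiments, keyed 'exp1' | 'exp2' | 'exp3'.

    Two washes each; wash amounts are per-wash cake *void* volumes, so
    reported ECV checkpoints are void volumes x porosity.  The wash-1
    mixture ratio for exp1 is a 50:50 default (unpublished); exp2 is the
    published 50:50 and exp3 the published 20:80.
    """
    if name not in _EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; choose from {EXPERIMENT_NAMES}")
    (cryst, wash, solid, solvent, api, acet, met,
     porosity, alpha, d50_um, vv, w1frac) = _EXPERIMENTS[name]
    feed = FeedSuspension(
        solid_api_mass=solid,
        dissolved_api_mass=api,
        solvent_masses={cryst: solvent},
        dissolved_impurity_masses={"acetanilide": acet, "metacetamol": met},
        crystal_density=PARACETAMOL_CRYSTAL_DENSITY,
        solvent_densities=dict(_SOLVENT_DENSITIES),
        impurity_densities=dict(_IMPURITY_DENSITIES),
    )
    return Experiment(
        name=name,
        cryst_solvent=cryst,
        wash_solvent=wash,
        feed=feed,
        porosity=porosity,
        pressure_drop=200.0e2,  # 200 mbar
        cake_resistance=alpha,
        particle_d50=d50_um * 1e-6,
        void_volumes_per_wash=vv,
        n_washes=2,
        wash1_cryst_fraction=w1frac,
    )
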