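"""Solvent property tables and solubility data.

A :class:`Solvent` is one row of a solvent screening table: the ambient
physicochemical properties (density, viscosity, melting/boiling point,
vapor pressure, enthalpy of vaporization) plus the safety attributes used
by the wash-solvent filters — the ICH residual-solvent class (1 = avoid,
3 = low risk) and the six GSK solvent-guide sustainability scores (1-10,
higher is better).  Any attribute may be *unknown* (``None``); unknown
values are never zero-filled, and downstream filters let unknowns pass
(the ICH filter being the documented exception, in strict mode).

Solubilities are stored internally in g solute per 100 g solvent; g/g is
accepted at the boundary and converted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GSK_AXES",
    "Solvent",
    "SolventTable",
    "SolubilityTable",
    "convert_solubility",
    "read_solvent_table",
    "write_solvent_table",
    "read_solubility_table",
    "write_solubility_table",
    "generate_fixture_table",
    "normalize_name",
]

#: The six GSK solvent selection guide axes, each scored 1-10.
GSK_AXES = (
    "waste",
    "environment",
    "health",
    "flammability",
    "reactivity",
    "life_cycle",
)

_UNIT_FACTORS = {"g_per_100g": 1.0, "g_per_g": 100.0}


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace-normalized solvent name key."""
    return " ".join(name.split()).lower()


def convert_solubility(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a solubility between g/100 g and g/g bases.

    g/g = (g/100 g) / 100.  The conversion is exact up to floating point
    and round-trips to 1e-12 relative.
    """
    if value < 0:
        raise ValueError(f"solubility must be non-negative, got {value}")
    for unit in (from_unit, to_unit):
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"unknown solubility unit {unit!r}")
    # internal canonical basis: g per 100 g solvent
    return value * _UNIT_FACTORS[from_unit] / _UNIT_FACTORS[to_unit]


@dataclass(frozen=True)
class Solvent:
    """One solvent screening-table row.  ``None`` marks an unknown value."""

    name: str
    density: float | None = None  # g/mL at ambient temperature
    viscosity: float | None = None  # Pa.s
    melting_point: float | None = None  # degC
    boiling_point: float | None = None  # degC
    vapor_pressure: float | None = None  # Pa
    enthalpy_vaporization: float | None = None  # kJ/mol
    ich_class: int | None = None  # 1..3
    gsk_scores: Mapping[str, int | None] = field(default_factory=dict)
    legislation_flag: bool | None = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("solvent name must be non-empty")
        if self.density is not None and self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        if self.viscosity is not None and self.viscosity <= 0:
            raise ValueError(f"{self.name}: viscosity must be > 0")
        if (
            self.melting_point is not None
            and self.boiling_point is not None
            and not self.melting_point < self.boiling_point
        ):
            raise ValueError(f"{self.name}: melting point must lie below boiling point")
        if self.ich_class is not None and self.ich_class not in (1, 2, 3):
            raise ValueError(f"{self.name}: ICH class must be 1, 2 or 3")
        scores = dict(self.gsk_scores)
        for axis, score in scores.items():
            if axis not in GSK_AXES:
                raise ValueError(f"{self.name}: unknown GSK axis {axis!r}")
            if score is not None and not 1 <= score <= 10:
                raise ValueError(f"{self.name}: GSK score {axis}={score} outside 1-10")
        object.__setattr__(self, "gsk_scores", scores)

    def gsk_score(self, axis: str) -> int | None:
        return self.gsk_scores.get(axis)


class SolventTable:
    """Ordered, name-unique collection of :class:`Solvent`."""

    def __init__(self, solvents: Iterable[Solvent], provenance: str = ""):
        self.solvents: list[Solvent] = list(solvents)
        self.provenance = provenance
        self._index: dict[str, Solvent] = {}
        for s in self.solvents:
            key = normalize_name(s.name)
            if key in self._index:
                raise ValueError(f"duplicate solvent name {s.name!r}")
            self._index[key] = s

    def __len__(self) -> int:
        return len(self.solvents)

    def __iter__(self) -> Iterator[Solvent]:
        return iter(self.solvents)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._index

    def get(self, name: str) -> Solvent:
        key = normalize_name(name)
        if key not in self._index:
            raise KeyError(f"solvent {name!r} not in table")
        return self._index[key]

    def names(self) -> list[str]:
        return [s.name for s in self.solvents]


_NUMERIC_COLUMNS = (
    "density",
    "viscosity",
    "melting_point",
    "boiling_point",
    "vapor_pressure",
    "enthalpy_vaporization",
)


def _parse_cell(raw, column: str, row: int, kind=float):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        return None
    try:
        return kind(float(raw)) if kind is int else kind(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"row {row}: non-numeric value {raw!r} in column {column!r}"
        ) from exc


def read_solvent_table(path) -> SolventTable:
    """Read a solvent property table from CSV (empty cell = unknown)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    if "name" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'name'")
    solvents = []
    for i, record in enumerate(df.to_dict("records")):
        row = i + 2  # 1-based, after header
        kwargs = {"name": str(record["name"]).strip()}
        for col in _NUMERIC_COLUMNS:
            if col in df.columns:
                kwargs[col] = _parse_cell(record[col], col, row)
        if "ich_class" in df.columns:
            kwargs["ich_class"] = _parse_cell(record["ich_class"], "ich_class", row, int)
        scores = {}
        for axis in GSK_AXES:
            col = f"gsk_{axis}"
            if col in df.columns:
                scores[axis] = _parse_cell(record[col], col, row, int)
        kwargs["gsk_scores"] = scores
        if "legislation_flag" in df.columns:
            raw = str(record["legislation_flag"]).strip().lower()
            kwargs["legislation_flag"] = None if raw == "" else raw in ("1", "true", "yes")
        solvents.append(Solvent(**kwargs))
    return SolventTable(solvents, provenance=str(path))


def write_solvent_table(table: SolventTable, path) -> None:
    """Write a solvent table to CSV; unknowns become empty cells."""
    rows = []
    for s in table:
        row: dict = {"name": s.name}
        for col in _NUMERIC_COLUMNS:
            row[col] = getattr(s, col)
        row["ich_class"] = s.ich_class
        for axis in GSK_AXES:
            row[f"gsk_{axis}"] = s.gsk_scores.get(axis)
        row["legislation_flag"] = s.legislation_flag
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


class SolubilityTable:
    """Records of (solute, solvent, temperature degC) -> solubility g/100 g."""

    def __init__(self, records: Iterable[tuple[str, str, float, float]]):
        self._data: dict[tuple[str, str, float], float] = {}
        for solute, solvent, temperature, solubility in records:
            if solubility < 0:
                raise ValueError(
                    f"negative solubility {solubility} for ({solute}, {solvent})"
                )
            key = (normalize_name(solute), normalize_name(solvent), float(temperature))
            if key in self._data:
                raise ValueError(
                    f"duplicate solubility record for ({solute}, {solvent}, {temperature})"
                )
            self._data[key] = float(solubility)

    def __len__(self) -> int:
        return len(self._data)

    def get(self, solute: str, solvent: str, temperature: float) -> float:
        """Solubility in g/100 g solvent."""
        key = (normalize_name(solute), normalize_name(solvent), float(temperature))
        if key not in self._data:
            raise KeyError(f"no solubility record for {key}")
        return self._data[key]

    def records(self) -> list[tuple[str, str, float, float]]:
        return [(*k, v) for k, v in sorted(self._data.items())]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records(),
            columns=["solute", "solvent", "temperature_C", "solubility_g_per_100g"],
        )


def read_solubility_table(path, units: str = "g_per_100g") -> SolubilityTable:
    """Read a solubility CSV; values are normalized internally to g/100 g.

    Expected columns: solute, solvent, temperature_C, solubility; an
    optional per-row ``units`` column overrides the ``units`` argument.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    required = {"solute", "solvent", "temperature_C", "solubility"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for rec in df.to_dict("records"):
        row_units = str(rec.get("units", units) or units)
        value = convert_solubility(float(rec["solubility"]), row_units, "g_per_100g")
        records.append((str(rec["solute"]), str(rec["solvent"]), float(rec["temperature_C"]), value))
    return SolubilityTable(records)


def write_solubility_table(table: SolubilityTable, path) -> None:
    df = table.to_frame()
    df["units"] = "g_per_100g"
    df = df.rename(columns={"solubility_g_per_100g": "solubility"})
    df.to_csv(path, index=False)


def generate_fixture_table(
    seed: int, n_solvents: int, n_solutes: int
) -> tuple[SolventTable, SolubilityTable]:
    """Generate a reproducible synthetic screening table plus solubilities.

    Emulates a large curated solvent list for filter and ranking tests:
    properties are drawn uniformly (log-uniformly where the range spans
    decades) over ranges that straddle every wash-filter threshold, and
    the first rows are forced to violate each filter in turn so that a
    fixture of any size exercises every rejection path.  Solubilities are
    log-uniform over [1e-3, 50] g/100 g at 22 degC.
    """
    if n_solvents < 2:
        raise ValueError("n_solvents must be >= 2")
    rng = np.random.default_rng(seed)
    solvents = []
    for i in range(n_solvents):
        density = rng.uniform(0.6, 1.6)
        viscosity = 10 ** rng.uniform(-4, math.log10(0.2))
        bp = rng.uniform(30.0, 250.0)
        mp = bp - rng.uniform(50.0, 200.0)
        vp = 10 ** rng.uniform(1, 5)
        dhvap = rng.uniform(20.0, 60.0)
        ich = int(rng.integers(1, 4))
        scores = {axis: int(rng.integers(1, 11)) for axis in GSK_AXES}
        # forced filter violators (one per rejection path)
        if i == 0:
            ich = 1  # ICH rejection
        elif i == 1:
            bp, mp = 28.0, -90.0  # boiling point within 10 degC of 22 degC wash
        elif i == 2:
            density = 1.55  # density-inversion risk against light solvents
        elif i == 3:
            viscosity = 0.15  # above the 0.09 Pa.s threshold
        elif i == 4:
            vp = 5.0e4  # above the 10 kPa vapor-pressure threshold
        elif i == 5:
            mp, bp = 15.0, 180.0  # melting point above 0 degC
        elif i == 6:
            scores["health"] = 2  # GSK axis at a flagged (<=3) level
        solvents.append(
            Solvent(
                name=f"solvent{i:03d}",
                density=round(density, 4),
                viscosity=round(viscosity, 6),
                melting_point=round(mp, 2),
                boiling_point=round(bp, 2),
                vapor_pressure=round(vp, 2),
                enthalpy_vaporization=round(dhvap, 2),
                ich_class=ich,
                gsk_scores=scores,
            )
        )
    records = []
    for j in range(n_solutes):
        for s in solvents:
            value = 10 ** rng.uniform(-3, math.log10(50.0))
            records.append((f"solute{j}", s.name, 22.0, round(value, 6)))
    return SolventTable(solvents, provenance=f"synthetic fixture (seed={seed})"), SolubilityTable(records)
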