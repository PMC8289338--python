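"""Binary solubility curves along the crystallization->wash gradient.

A :class:`BinaryCurve` gives the solubility (g/100 g solvent) of one
solute as a function of the wash-solvent mass fraction in a
crystallization/wash solvent mixture.  An interior maximum on such a
curve signals an API dissolution risk during washing: the cake liquor
passes through a composition in which the API is more soluble than in
either pure solvent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["BinaryCurve", "build_binary_curve", "solubility_at", "detect_maximum"]

_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass(frozen=True)
class BinaryCurve:
    """Solubility of ``solute`` vs wash mass fraction in [0, 1].

    ``interpolation`` is either ``shape_preserving_cubic`` (monotone
    piecewise cubic between knots, no new extrema) or ``log_linear``
    (linear in log solubility, natural for antisolvent gradients; all
    knot solubilities must be positive).
    """

    solute: str
    cryst_solvent: str
    wash_solvent: str
    fractions: tuple[float, ...]
    solubilities: tuple[float, ...]
    interpolation: str = "shape_preserving_cubic"

    def __call__(self, wash_fraction) -> np.ndarray | float:
        return solubility_at(self, wash_fraction)


def build_binary_curve(
    knots,
    interpolation: str = "shape_preserving_cubic",
    solute: str = "API",
    cryst_solvent: str = "crystallization",
    wash_solvent: str = "wash",
) -> BinaryCurve:
    """Build a curve from (wash_mass_fraction, solubility g/100 g) knots.

    Fractions must be strictly increasing and include the endpoints 0 and
    1 (the pure-solvent solubilities); solubilities must be >= 0.
    """
    knots = sorted(knots)
    fractions = [float(f) for f, _ in knots]
    sols = [float(s) for _, s in knots]
    if len(knots) < 2:
        raise ValueError("need at least 2 knots")
    if any(b - a <= 0 for a, b in zip(fractions, fractions[1:])):
        raise ValueError("wash fractions must be strictly increasing (no duplicates)")
    if fractions[0] != 0.0 or fractions[-1] != 1.0:
        raise ValueError("knots must include the endpoints 0 and 1")
    if any(s < 0 for s in sols):
        raise ValueError("solubilities must be non-negative")
    if interpolation == "log_linear" and any(s <= 0 for s in sols):
        raise ValueError("log_linear interpolation requires positive solubilities")
    if interpolation not in ("shape_preserving_cubic", "log_linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return BinaryCurve(
        solute, cryst_solvent, wash_solvent, tuple(fractions), tuple(sols), interpolation
    )


def solubility_at(curve: BinaryCurve, wash_fraction) -> np.ndarray | float:
    """Evaluate the curve at wash fraction(s) in [0, 1] -> g/100 g."""
    x = np.asarray(wash_fraction, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("wash fraction must lie in [0, 1]")
    f = np.asarray(curve.fractions)
    s = np.asarray(curve.solubilities)
    if curve.interpolation == "log_linear":
        out = np.exp(np.interp(x, f, np.log(s)))
    else:
        if len(f) == 2:  # pchip on two points is a straight line
            out = np.interp(x, f, s)
        else:
            out = PchipInterpolator(f, s)(x)
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(wash_fraction) else out


def detect_maximum(
    curve: BinaryCurve, rel_tol: float = 1e-6
) -> tuple[bool, float | None]:
    """Detect an interior solubility maximum (API dissolution risk).

    Evaluates the curve on a fixed 1001-point grid; returns True (with
    the grid argmax location) iff the interior maximum exceeds *both*
    endpoint values by the relative tolerance.
    """
    values = solubility_at(curve, _GRID)
    end = max(values[0], values[-1])
    interior = values[1:-1]
    idx = int(np.argmax(interior)) + 1
    if values[idx] > end * (1.0 + rel_tol):
        return True, float(_GRID[idx])
    return False, None
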