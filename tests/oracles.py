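"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results through different code
paths than the library (pairwise comparisons, O(n^2) dominance checks,
hand-written closed forms) so that implementation and oracle cannot
share a bug.
"""

from __future__ import annotations

import math


def dominance_fronts(points: list[tuple[float, ...]]) -> list[int]:
    """O(n^2) non-dominated front index (0-based) per point.

    All objectives are minimized.  A point dominates another if it is no
    worse in every objective and strictly better in at least one.  Front
    k is the non-dominated set after removing fronts < k.
    """

    def dominates(a, b):
        return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))

    remaining = set(range(len(points)))
    fronts = [-1] * len(points)
    level = 0
    while remaining:
        current = {
            i
            for i in remaining
            if not any(dominates(points[j], points[i]) for j in remaining if j != i)
        }
        for i in current:
            fronts[i] = level
        remaining -= current
        level += 1
    return fronts


def selection_sort_ranking(entries, better):
    """Exhaustive pairwise-comparator ordering (selection sort)."""
    pool = list(entries)
    out = []
    while pool:
        best = pool[0]
        for e in pool[1:]:
            if better(e, best):
                best = e
        out.append(best)
        pool.remove(best)
    return out


def filtration_time_closed_form(mu, alpha, w, area, dp, rm, volume):
    """Constant-pressure Darcy filtration time, evaluated by hand."""
    cake_term = mu * alpha * w * volume * volume / (2.0 * area * area * dp)
    medium_term = mu * rm * volume / (area * dp)
    return cake_term + medium_term


def washout_erfc(z, t, velocity, dispersion):
    """Semi-infinite washout profile c/c0 = 1/2 erfc((vt - z)/(2 sqrt(Dt)))."""
    return 0.5 * math.erfc((velocity * t - z) / (2.0 * math.sqrt(dispersion * t)))


def total_wash_inflow(spec, void_volume_mL, solvent_densities):
    """Per-solvent wash inflow masses (g), recomputed by hand.

    Wash mass = void volumes x void volume x mass-weighted density of
    the wash mixture (pure-solvent washes only).
    """
    inflow: dict[str, float] = {}
    for wash in spec.washes:
        rho = sum(f * solvent_densities[name] for name, f in wash.composition.items())
        mass = wash.void_volumes * void_volume_mL * rho
        for name, f in wash.composition.items():
            inflow[name] = inflow.get(name, 0.0) + mass * f
    return inflow


def conservation_error(feed_stream, result, spec, void_volume_mL, solvent_densities):
    """Max relative species imbalance of feed + wash inflow vs cake + filtrates."""
    lhs = dict(feed_stream.component_masses())
    for name, mass in total_wash_inflow(spec, void_volume_mL, solvent_densities).items():
        key = f"solvent:{name}"
        lhs[key] = lhs.get(key, 0.0) + mass
    rhs = dict(result.cake.component_masses())
    streams = [result.filtration_filtrate] + [cp.filtrate for cp in result.checkpoints]
    for stream in streams:
        for key, mass in stream.component_masses().items():
            rhs[key] = rhs.get(key, 0.0) + mass
    err = 0.0
    for key in set(lhs) | set(rhs):
        ref = max(lhs.get(key, 0.0), 1e-30)
        err = max(err, abs(rhs.get(key, 0.0) - lhs.get(key, 0.0)) / ref)
    return err
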