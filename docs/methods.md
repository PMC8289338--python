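# Methods

This note documents the models behind `isoselect`, the assumptions they
make, the defaults they ship with, and the choices taken where the
design was genuinely open.

## Scope and assumptions

The package addresses the *isolation* of a crystallized API: filtration
of the slurry, washing of the cake, and the solvent-selection decisions
upstream of both.  Throughout:

- Solubilities are inputs (tabulated, predicted elsewhere, or measured);
  the package performs no quantum-chemical or group-contribution
  estimation.  The canonical internal unit is g solute per 100 g
  solvent; g/g is converted at the boundary (`g/g = (g/100 g)/100`).
- No kinetics: dissolution and precipitation enter only as *risk flags*
  from equilibrium solubility comparisons, never as rate processes.
- Ideal mixing: liquid densities are mass-weighted averages of the pure
  component densities, with dissolved solutes contributing at their
  crystal densities.  This convention reproduces the case-study
  filtration yields to < 0.1 percentage points.
- All crystallization/wash pairs are treated as miscible unless the
  user flags otherwise; drying is out of scope.

## Crystallization ranking

On a fixed solvent basis `m_solv` (default 100 g) with hot loading
`x_hot` and isolation-temperature solubility `x_cold` (both g API per g
solvent): return = `(x_hot − x_cold)·m_solv`, yield =
`100·(x_hot − x_cold)/x_hot`, solvent ratio = `m_solv/return`.  The
bundled case-study candidates back-solve `x_hot` from the published
returned masses (`x_hot = x_cold + return/100`); this direction is
numerically robust where back-solving from a 2-decimal yield is not
(at 98 % yield a 0.01 pp yield rounding moves the return by ~0.1 g).
The 100 g solvent basis of those triples is an inference from their
mutual consistency and is labelled as such.

Candidates land on a 3×3 grid of yield bands (edges 90 %, 70 %,
left-closed) × solvent-ratio bands (edges 10, 20 g/g, left-closed) and
sort by the category order 1, 4, 7, 2, 5, 8, 3, 6, 9 (ties: higher
yield, then lower ratio, then name).  The numeric band edges are
configurable defaults — only the category order and the 3.5/10 g/g
suspension limits are fixed rules.  Below 3.5 g solvent/g product the
suspension is an unstirred paste and the candidate is excluded; above
10 g/g it is kept but flagged as dilute.  The flag deliberately does
not reorder the list: the volume bands of the grid already penalize
dilute processes, and making demotion a sort key would invert the
stated category order (category 4 always sits above 10 g/g under the
default edges).

## Wash solvent selection

Filters attach flags; they never delete candidates, so an audit can
always show *why* a solvent fell out.  Unknown property values pass any
filter they cannot be evaluated against — except the ICH filter, which
in strict mode fails unknowns (a solvent of unknown toxicity class is
not presumed safe).  The cumulative filter levels mirror the screening
practice: level 1 none; level 2 miscibility, density inversion
(ρ_wash > 1.3·ρ_cryst), relative API solubility; level 3 adds melting
point < 0 °C, boiling point 60–130 °C, viscosity < 0.09 Pa·s, vapor
pressure < 10 kPa; level 4 adds ICH class 3 and all six GSK
sustainability scores > 3.

The Δ-solubility classes for a candidate wash
(x = impurity − API solubility, g/100 g) partition the axis
left-closed: class 1 on [0, 1), 2 on [1, 10), 3 on [10, 20), 4 on
[20, ∞); x < 0 means washing cannot fully purify the cake — with < 2
mol % impurity load at least 3 equivalent cake volumes are advised,
with ≥ 2 mol % the crystallization itself should be revised (or > 5–6
cake volumes spent).

Ranking of the unflagged pool uses NSGA-II *non-dominated sorting
only*: the candidate set is finite, so no genetic search is run, and
crowding distance is replaced by a deterministic within-front order
(descending mean impurity solubility, then ascending API solubility,
then name) so that repeated runs give identical lists.  Each impurity
is its own maximization objective.  Two advisory scores are reported
but never filtered on, because no numeric bound exists for them: the
wash/mother-liquor viscosity ratio, and a drying-friendliness z-score
`z(V_p) − z(T_b) − z(ΔH_vap)` computed over the candidate pool.

## Binary solubility curves

Solubility along the crystallization→wash gradient is a user-supplied
knot set on wash mass fraction ∈ [0, 1] with both endpoints required.
Default interpolation is shape-preserving piecewise cubic (PCHIP:
exact at knots, no new extrema between them); `log_linear` is offered
for sparse two-knot antisolvent data, where solubility decay is close
to exponential in composition.  Interior-maximum detection evaluates a
fixed 1001-point grid and reports a dissolution risk when the interior
maximum exceeds both endpoints by a 1e-6 relative tolerance — a grid
rather than a root-finder for determinism on arbitrary knot sets.

## Model A: phase split + ideal displacement washing

Filtration is a mass-balance split.  Cake void volume
`V_v = (m_solid/ρ_c)·ε/(1−ε)`; at the dryland endpoint the cake keeps
`V_v·ρ_ML` grams of mother liquor (saturation 1), at breakthrough a
user-set residual saturation < 1.  Cake and filtrate liquids share the
mother-liquor composition; every species is conserved exactly.

Washing is discretized into tranches (default 10 per wash).  Each
tranche of wash mass (1/n of the wash) **displaces an equal mass of the
original residual mother liquor to the filtrate at its undiluted
composition** until that liquor is exhausted; thereafter tranches
displace the current mixed cake liquid.  Meanwhile every tranche mixes
fully into the cake voids, and this *post-mixing* composition — located
on the binary curves — is what drives the risk flags.  The dual
accounting is deliberate: plug-front filtrate composition is the only
reading of ideal displacement under which the filtrate runs clean after
roughly one pore volume and cumulative removal reaches exactly 100 %;
a fully-mixed filtrate tails exponentially forever.  A corollary is
that boundary-checkpoint removals are independent of the tranche count
(10 vs 1000 agree to better than 1e-6); discretization affects only
the granularity of flag timing.

Flags: API dissolution risk fires when the equilibrium-dissolvable API
(curve value × solvent mass/100) exceeds the dissolved API present at
the end of filtration; impurity precipitation risk fires when a
dissolved impurity exceeds its solubility cap.  By default the flags
are advisory and the mass balance is untouched (consistent with the
no-kinetics assumption).  An optional worst-case mode
(`precipitation="retain"`) converts the super-solubility excess into
unwashable solid retained in the cake, bounding the achievable purity
from below; it is not the default because retention would also break
the ordering guarantee that the dispersion model never removes *more*
than the ideal-displacement model.

Wash amounts are specified in cake **void volumes**; reported "ECV"
checkpoints are void volumes × porosity, matching the convention of the
validation experiments (e.g. two 2-void-volume washes at ε = 0.44 give
checkpoints 0.88 and 1.76 ECV).  Both numbers appear in results.

## Model B: Darcy filtration + advection–dispersion washing

Constant-pressure cake filtration follows
`t(V) = μαwV²/(2A²ΔP) + μR_m V/(AΔP)`; the flow-rate curve is its
derivative.  The specific cake resistance α is the measured value when
available, else Kozeny–Carman `α = 180(1−ε)/(ρ_c φ² d² ε³)` from the
mean particle size d and sphericity φ.  The medium resistance defaults
to 1e6 1/m.

Washing solves, per dissolved species, the one-dimensional
advection–dispersion equation on the cake height with interstitial
velocity v = u/ε (u derived from the Darcy flow through the fully
formed cake at the wash pressure), a Danckwerts-type advective inlet at
the wash composition, and free outflow at the medium.  The scheme is
explicit finite-volume: upwind advection, central dispersion, CFL ≤ 0.5
with automatic step reduction — chosen for transparency and exact
telescoping mass conservation, and verified against the closed-form
washout profile ½·erfc((vt−z)/(2√(D_L t))) (< 1 % mid-domain) and the
plug-flow limit as D_L → 0.  Every liquid component (solvents included)
is a transported scalar, so effluent streams assemble componentwise and
conservation holds for each species to better than 1e-6 relative.

The axial dispersion coefficient defaults to 1e-9, interpreted as m²/s
(the literature value it descends from is printed unitless).  At
bench-scale Darcy velocities this makes the wash front nearly a plug:
removal approaches 100 % but a strictly positive residual always
remains in the cake — the qualitative distinction from model A.  Risk
flags are evaluated from the cake-average composition on the same
binary curves as model A (advisory only); a `strict_paper` switch
disables this gradient-solubility coupling to mimic a formulation in
which model B lacks it.

Filter geometry (area, hence cake height) is configuration: the
default 20 mm-diameter cylindrical port is a placeholder for whatever
dead-end filtration unit is used, never hard-coded into the physics.

Yield definitions, both models: filtration yield = % of fed API (solid
+ dissolved) retained in the cake after the phase split; washing yield
= the same ratio at the end of washing; impurity removal = % of the fed
impurity mass no longer in the cake (so the filtration split already
contributes).  No published formula exists for these percentages; these
definitions reproduce the case-study filtration yields for the
2-propanol and 3-methyl-1-butanol experiments to < 0.1 pp.  The ethanol
experiment's published input fraction (0.2599) is not reproducible from
its own component masses (which give 0.2256, matching the experiment
column elsewhere); the component masses are taken as authoritative.

## Bundled data and synthetic fixtures

`datasets` builds the case-study tables programmatically: curated
literature-typical solvent properties, published pure-solvent
solubilities (entries printed as "<0.005" are stored at the 0.005
bound), and the three validation experiments.  Two gaps are filled with
labelled synthetic values: the impurity solubilities in the pure
*crystallization* solvents (plausible free-solubility magnitudes for
the alcohols: both impurities dissolve readily) and the ethanol
experiment's wash-1 mixture ratio (50:50).  Both affect only risk-flag
positioning, not the displacement mass balance.  Binary curves for the
experiments are two-knot log-linear, anchored at the pure-solvent
endpoints.

`generate_fixture_table` emulates a large screening list for filter and
ranking tests: properties uniform (log-uniform across decades) over
ranges straddling every filter threshold — boiling point 30–250 °C,
density 0.6–1.6 g/mL, viscosity 1e-4–0.2 Pa·s, vapor pressure
10–1e5 Pa, ICH ∈ {1,2,3}, GSK 1–10, solubilities log-uniform on
[1e-3, 50] g/100 g — with the first rows forced to violate each filter
in turn, so any fixture size exercises every rejection path.  Output is
deterministic per seed.  What the fixtures do *not* emulate: correlated
real-solvent properties (density/viscosity/boiling point co-vary in
reality), temperature dependence, or measured miscibility — so passing
filter tests demonstrates the logic, not chemical accuracy on real
lists.

## Numerical choices and degenerate inputs

- Solvent names match case-insensitively after whitespace
  normalization (published spellings vary).
- Zero return mass ⇒ yield 0 with an infinite solvent ratio; zero hot
  loading is a domain error.
- Flag comparisons use a 1e-9 relative + 1e-12 absolute guard so exact
  saturation does not flag through float noise.
- Problem sizes: dispersion washing uses 200 grid cells by default
  (refining to 800 moves case-study removals by far less than 0.5 pp);
  the erfc verification uses 600 cells at a Peclet where physical
  dispersion dominates the scheme's numerical diffusion
  (`D_num ≈ v·Δz(1−CFL)/2`).

## Known limitations

- One-dimensional washing: no viscous fingering, channeling or
  fine-particle migration — all of which degrade real wash efficiency,
  so both simulators are optimistic about removal per wash volume.
- No deliquoring/gas breakthrough multiphase flow; breakthrough is a
  user-set residual saturation, not predicted.
- Binary (two-solvent) gradients only; no ternary composition spaces.
- The GSK scores and ICH classes are inputs; the scoring methodologies
  themselves are not reimplemented.
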