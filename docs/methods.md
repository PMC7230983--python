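# Methods

## Scope and modelling stance

`vesifuse` collects the closed-form, desk-scale models that describe
optical-tweezer manipulation of giant unilamellar vesicles: adhesion
geometry, volume-conserving fusion, osmotic bookkeeping, ternary
composition changes, nanoparticle heating and membrane-domain
coalescence. Everything is either a closed form or a small seeded
simulation; there is no image analysis, no force balance for the trap
itself, and no transport dynamics — the package computes end states and
audits conserved quantities, not trajectories.

## Adhesion geometry

Two identical vesicles adhering at contact angle ϑ are modelled as
truncated spheres sharing a flat patch, with the enclosed volume fixed at
the free-sphere value. The membrane area of each truncated sphere —
curved part plus the flat patch disc — relative to the free sphere is the
closed form

    f(ϑ) = (3 − cos ϑ) / (2^(2/3) (1 + cos ϑ)^(1/3) (2 − cos ϑ)^(2/3)) − 1.

Counting the patch disc as membrane is a modelling choice: with it, the
closed form is algebraically identical to the explicit truncated-sphere
construction, which the test suite verifies independently by solving the
volume-conservation equation numerically (`brentq`) on a 60-angle grid at
1e-9 relative tolerance. The formula is valid only for patches at or
below the equator (ϑ ≤ 90°); larger angles raise an error, as does any
attempt to build an adhesion pair from unequal vesicles — the unequal
case has a different geometry that this package deliberately does not
approximate.

Tension follows the linear elastic law Δτ = K_A · f(ϑ) with
K_A = 200 mJ/m² by default (typical fluid phosphatidylcholine bilayer).
The low-tension entropic (logarithmic) regime is not implemented. Note a
scale tension worth knowing: a 1% area strain under this law is ~2 mN/m,
whereas tens of µN/m correspond to strains of ~1e-4, i.e. contact angles
of only a few degrees. The package reports the linear-law value without
attempting to reconcile looser qualitative statements about the tension
scale.

Angles are radians throughout the library; the CLI accepts and prints
degrees.

## Fusion bookkeeping and outcome model

Volume conservation fixes the post-fusion radius at
(r₁³ + r₂³)^(1/3), and the fractional membrane-area deficit

    1 − (r₁³ + r₂³)^(2/3) / (r₁² + r₂²)

lies in [0, 1 − 2^(−1/3) ≈ 0.206], maximal for equal radii (verified by a
numeric scan at fixed total volume). Every `FusionEvent` record re-checks
volume conservation to 1e-12 relative tolerance at construction.

Osmolarity is van't Hoff bookkeeping, Σⱼ iⱼcⱼ, with defaults i = 1 for
sucrose and glucose and i = 2 for NaCl. The standard recipes ship as
constants: 0.75 M sucrose inside; 0.35 M glucose + 0.2 M NaCl
(0.75 Osm/L, iso-osmotic) or 0.4 M glucose + 0.2 M NaCl (0.8 Osm/L,
deflating) outside. Deflation uses the ideal-osmometer rule — membrane
permeable to water, impermeable to solutes — so the equilibrium volume
ratio is Osmᵢₙ/Osmₒᵤₜ (0.9375 for the deflating recipe). This is the
simplest model consistent with "osmotically deflated"; no graded
tension–outcome curve is modelled because only two discrete conditions
are characterised.

The outcome classifier has three rules, in order: laser power at or below
the 150 mW fusion threshold rejects the event (the 20–100 mW range is
manipulation-only); an osmotic ratio below 1 − 1e-6 forces a disorderly
outcome with certainty; otherwise the outcome is clean with a single
Bernoulli probability, default 0.82. All three numbers are config
defaults, overridable per call. Disorderly events record only the class
and the area-deficit budget available for internal structures; the
number and size distribution of internal daughter vesicles is not
simulated — no governing mechanism is available to implement. Whether
non-clean iso-osmotic events correlate with size, power or particle count
is unknown, so the classifier deliberately carries no covariates.

## Composition arithmetic and phase lookup

Compositions are non-negative DOPC/EggSM/Chol parts with derived mole
fractions. Two mixing rules are exposed:

- `mix_amounts` — weighted componentwise summation of parts. Equal
  weights on 1:1:0 and 1:1:3 give 2:2:3, the bench arithmetic for fusing
  identical vesicles, and the default rule.
- `mix_fractions` — area-weighted averaging of mole fractions, assuming
  equal area per molecule. This rule is mole-conserving; the same pair
  gives 7:7:6.

The two disagree because ratio notation is ambiguous about whether parts
are normalised per vesicle before summing; neither rule is asserted as
correct, and the discrepancy is surfaced in docstrings rather than
hidden.

`to_integer_ratio` rationalises mole fractions via
`Fraction.limit_denominator` (bound 1000), reduces by the gcd, verifies
the triple reproduces the fractions to 1e-6 relative tolerance, and
otherwise falls back to rounded scaled fractions.

Phase lookup embeds the simplex with DOPC, EggSM and Chol at the
bottom-left, bottom-right and top vertices (x = EggSM + Chol/2,
y = (√3/2)·Chol, unit edge) and uses shapely point-in-polygon tests
against labelled regions. Boundary points go to the first region listed
in the diagram file — a deterministic, documented tie-break. Points
outside all regions return the explicit label `"unassigned"`, never a
silent default. The shipped diagram is schematic: three
cholesterol-fraction bands (gel/liquid below 15 mol% Chol, Lo/Ld between
15 and 50, uniform liquid above 50) chosen so the four canonical
compositions (1:1:0, 1:1:3, 2:2:3, 1:1:1) land in their experimentally
observed phases. Its provenance string says so; users doing quantitative
work should load an empirical diagram. Tie-lines, lever-rule area
fractions and temperature-dependent boundaries are out of scope.

## Nanoparticle heating

The steady-state point-absorber solution for a particle of radius a
absorbing power P in a medium of conductivity k:
ΔT_s = P/(4πka) at the surface, flat inside (isothermal-metal
approximation), ΔT_s·a/r outside. Defaults: a = 75 nm (150 nm gold
particles), k = 0.6 W/(m·K) (water). Absorbed power is an input, never
derived from laser power — that conversion needs an absorption
cross-section outside this model. The few-degree bulk warming at the
laser focus is likewise a configured constant (default 5 °C, typical
estimates 4–6 °C), never computed. `hot_zone_extent` inverts the field in
closed form (r* = a·ΔT_s/threshold); a threshold above the surface rise
returns `None` (no hot zone), and a zero threshold is rejected because a
1/r field never reaches it. The tests include a reachable-regime check —
parameters exist (e.g. a 10 nm particle absorbing 9 µW) for which the
surface rise exceeds 100 °C while the rise 2.5 µm away stays below
1 °C — asserted as an existence statement about heat localisation, not a
universal law.

## Domain coalescence

Domains are in-plane spherical caps: area A = 2πR²(1 − cos α), boundary
L = 2πR sin α, capped at a hemisphere (α ≤ 90°); larger caps and merges
that would exceed the hemisphere raise errors. Line energy is γ·ΣL in
pN·µm. Because L(A) ∝ √(u(2−u)) with u = 1 − cos α is concave through the
origin, boundary length is subadditive in area, so every same-phase merge
releases line energy — property-tested over random areas and re-checked
in each `MergeEvent` record.

The experimentally observed out-of-plane "bulging" of domains, and the
inter-domain repulsion that kinetically stabilises many-domain states, is
represented only by a `kinetically_trapped` flag meaning "no spontaneous
merging; merges occur only when commanded" — no repulsion potential is
available to implement. The merge scheduler is therefore an abstract
actuator replaying a user-specified order (emulating domains dragged
together with the trap); no trap force is computed. n domains always
collapse in exactly n − 1 events with the same final area whatever the
order. Cross-phase merges are rejected rather than modelled.

Line tension versus temperature uses a linear ramp vanishing at the
miscibility temperature, γ(T) = γ_ref·max(0, (T_c − T)/(T_c − T_ref)) —
the simplest monotone form with the right anchors; no measured curve is
fitted.

## Synthetic-data generator

The generator emulates the experimental material: log-normal vesicle
diameters with median 5 µm and log-scale shape 0.25 (log-normal chosen
for positivity; only the ~5 µm scale is characterised, so the shape is a
package choice), compositions drawn from a user probability table,
0.75 M sucrose against the iso-osmotic buffer by default, a 20%
excess-area fraction and 50% nanoparticle-labelling fraction as neutral
defaults, and a clean-fusion probability of 0.82. Campaigns pair
shuffled vesicles without replacement and run each pair through the
outcome classifier; event tables carry a volume audit. Domain
configurations partition the requested liquid-disordered area
(fraction ≤ 0.5 of the vesicle, so merged caps stay within the
hemisphere model) with a flat Dirichlet(1,…,1) draw — a uniform simplex,
since no size distribution is characterised — and the last area is set by
subtraction so totals are conserved exactly against rounding.

Every generator consumes a single `numpy.random.Generator` seeded per
call and writes the seed into its output, so all tables are
bit-reproducible. What the generators do **not** emulate: optical
artefacts, image noise, vesicle polydispersity beyond log-normal,
correlations between size and outcome, or the morphology of disorderly
products. Tests passing on synthetic data therefore validate the models'
internal consistency and statistical contracts, not agreement with any
particular microscope recording.

## Numerical choices

- Contact angles validated to [0, π/2] with 1e-12 slack; `min/max`
  clamping guards `acos`/`asin` against rounding at the domain edges.
- The geometric oracle in the tests solves volume conservation with
  `scipy.optimize.brentq` at xtol/rtol 1e-15 and compares at 1e-9
  relative tolerance; the oracle never calls the closed form it checks.
- Statistical tests use three binomial standard errors (10,000 trials
  for the clean-fraction check) under fixed seeds, and hypothesis
  property tests run derandomised.
- Test problem sizes (60-angle grids, 200-vesicle populations, 40
  replicate campaigns) keep the whole suite under ~10 s while leaving
  the statistical checks well-powered.

## Known limitations

- Unequal-vesicle adhesion, pore dynamics, pearling mechanics, tubule
  retraction and trap-force magnitudes are out of scope by design.
- The linear tension law is wrong at very low tensions (entropic regime).
- The shipped phase diagram is illustrative; its boundaries carry no
  experimental uncertainty because they are not experimental.
- The heating model ignores the membrane, interfacial (Kapitza)
  resistance, and collective heating from multiple particles.
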