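# Methods

## Steady-state diffusion model

A secreting cell is modelled as a spherically symmetric Gaussian source of
width W_s (≈ the cell width, 1 µm) in Fick's second law with diffusion
coefficient D. The steady state around one cell is
N(r) = P/(2πDr) · φ(r/(√2 W_s)) with φ the error function: far from the
cell this is the bare point-source field P/(2πDr); at the origin it tends
to the finite limit P/(√2 π^{3/2} D W_s).

Two origin prefactors circulate for this limit — 1/(√2 π^{3/2}) from the
small-argument series of φ, and 1/(2π)^{3/2}, exactly half of it, from a
truncated Taylor treatment. The field uses the series-consistent value so
the profile is continuous through the switch point (r < 10⁻⁶ W_s, where the
ratio form becomes numerically indeterminate); both constants are exported
(`ORIGIN_PREFACTOR_SERIES`, `ORIGIN_PREFACTOR_TAYLOR`) for comparison.
Continuity matters downstream: the minimum-thickness bisection probes
radii down to a single cell width.

For a colony, the concentration at the centre of a sphere of radius R with
uniform density n is the continuum sum of per-cell fields,
(P n / D) ∫₀ᴿ r φ(r/(√2 W_s)) dr, evaluated two independent ways:

- **Closed form** (the production route):
  (P n R²/2D) · [1 − (W_s²/R²) φ(R/(√2 W_s)) + √((2W_s/πR) e^{−(R/2W_s)²})].
  The last term is kept exactly as written, exponential inside the square
  root with exponent (R/2W_s)²; it underflows to zero for every packaged
  scenario (R/W_s ≥ 450), so its algebraic ambiguity is inert. A warning is
  emitted for R < 10 W_s where the bracket's approximations degrade.
- **Adaptive quadrature** (the independent oracle): `scipy.integrate.quad`
  at relative tolerance 10⁻¹⁰ with a 500-subdivision cap; the call raises
  if the reported error estimate exceeds tolerance. Closed form and
  quadrature agree to < 10⁻³ relative for R/W_s > 300 and < 10⁻² down to
  R/W_s = 50 (randomized test).

**Units.** All mathematics runs in CGS (cm, s, molecules, cm⁻³).
User-facing constructors accept mm (colony radius), µm (cell width) and
cells/mL (numerically identical to cells/cm³); concentrations are reported
in nM via 1 nM = 6.02214076 × 10¹¹ molecules/cm³. Conversions live in one
module (`units.py`) and round-trip to machine precision.

## Feasibility, calibration and minimum thickness

Quorum sensing is declared when N_threshold ≤ N_total, non-strict, so a
colony sitting exactly at threshold counts as activated. The threshold
itself is a free input with default 10 nM; the packaged scenarios instead
*calibrate* it — compute N_total at a reference point and use that value —
because the standard reference condition (P = 5000 molecules·cell⁻¹·s⁻¹,
n = 10⁶ cells/mL, W_s = 1 µm, minimum feasible thickness 0.45 mm at
D = 10⁻⁶ cm²/s) pins it to 8.406 nM.

N_total is strictly increasing in R, so the minimum biofilm thickness
R_min solves N_total(R) = N_threshold uniquely. The solver is plain
bisection (unconditionally convergent on a monotone, cheap function) with
tolerance 10⁻⁷ mm, tight enough that N_total at the returned root matches
the threshold to 10⁻⁶ relative. Bracket violations are reported naming the
failing side. Since N_total ≈ P n R²/2D to leading order, R_min scales as
√D — the calibrated table runs 0.45, 0.636, 0.779, 0.900, 1.006 mm for
D = 1…5 ×10⁻⁶ cm²/s. (Published roundings of the middle entries, 0.62 and
0.88 mm, sit 2–3 % off the model-exact values; the √D law fixes which is
exact.) N_total depends on P and n only through their product, so sweeps
over either at equal P·n are bitwise identical.

## Growth kinetics and coupling

Substrate θ (gCOD/mL) and cell density β (cells/mL) follow single-species
chemostat equations with Monod uptake:

    dθ/dt = (θ_in − θ)α − μ(θ)β
    dβ/dt = (γ μ(θ) − α)β − k_dec β,    μ(θ) = μ_max θ/(K_s + θ).

Dimensional bookkeeping of these forms makes μ a **per-cell substrate
uptake rate** (gCOD·cell⁻¹·h⁻¹): μβ is then substrate consumption per
volume, and γμ (yield γ in cells/gCOD times uptake) is the familiar
specific growth rate in h⁻¹. The defaults are chosen on that reading:

| parameter | default | meaning |
|---|---|---|
| θ_in = θ₀ | 5 × 10⁻³ gCOD/mL | substrate charge / inflow concentration |
| β₀ | 10⁴ cells/mL | inoculum |
| α | 0 h⁻¹ | dilution rate (0 = batch culture) |
| γ | 10⁹ cells/gCOD | biomass yield |
| K_s | 5.52 × 10⁻³ gCOD/mL | half-saturation (the quoted 55.2 on a 10⁻⁴ scale) |
| k_dec | 0.01 h⁻¹ | first-order decay |
| μ_max | 3 × 10⁻¹⁰ gCOD·cell⁻¹·h⁻¹ | per-cell uptake; γ·μ_max = 0.3 h⁻¹ |
| t_end, dt | 240 h, 0.5 h | horizon and reporting grid |

With these values a batch run shows all four canonical phases within
240 h: slow start from the small inoculum, exponential growth at ≈0.29 h⁻¹
net, a peak of ≈4.1 × 10⁶ cells/mL near 60 h when substrate depletes, and
first-order death thereafter. K_s is quoted in the same units as θ; the
comparative pair 55.2 vs 17 (×10⁻⁴ gCOD/mL) gives the expected ordering —
lower half-saturation grows faster at every time during the growth phase.
μ_max = 0 is accepted (no growth), which yields the exact washout solution
β(t) = β₀ e^{−(α+k_dec)t} used as an integrator check.

Two exact invariants anchor the integration: in batch mode
(α = k_dec = 0) the yield-weighted total β + γθ is conserved, and when
γμ_max < α + k_dec the culture washes out monotonically. Integration uses
LSODA (stiff-capable, adaptive) at rtol 10⁻⁸ with component-wise atol
10⁻¹² of each state's scale; reporting times are an even grid interpolated
from the dense solution, so CSVs do not depend on adaptive step placement.
Tiny negative excursions are clipped to zero at reporting only, never
inside the integrator state.

**Coupling.** β(t) replaces the static density n in the colony formula at
every reported time; per-cell production P stays constant (the only
reading consistent with P's per-cell units). In the default
`density_and_radius` mode the colony also swells at constant packing
density, R(t) = R₀ (β/β₀)^⅓ with R₀ = 0.1 mm at the inoculum density —
the minimal assumption linking population to geometry; alternatives can be
added behind `coupling_mode` (the `density_only` mode holds R fixed, making
N_total exactly proportional to β). Radii are floored at one cell width so
transiently tiny populations stay in the model's domain. The coupled
signal N_total ∝ β·R(t)² ∝ β^{5/3} is a monotone transform of β, so its
peak coincides with (never precedes) the cell-density peak — the delayed
autoinducer maximum at the onset of the death phase.

## What the packaged scenarios do and do not show

Scenarios are code, not data: fixed parameter sets reproducing the
standard studies (diffusion sweep at 500 µm thickness, minimum-thickness
table, production-rate/density grids pinned at R = 1 mm, the 240 h growth
runs). They exercise the model under idealized conditions — uniform
spherical colonies, homogeneous D, constant per-cell production, single
species, no autoinducer degradation or feedback on production. Passing
tests demonstrate internal correctness of the mathematics and its
numerics, not that a real biofilm, with spatial heterogeneity and
regulatory feedback, will cross threshold at the predicted thickness.

## Numerical choices and limitations

- Bisection tolerance 10⁻⁷ mm; quadrature rtol 10⁻¹⁰; ODE rtol 10⁻⁸.
- The feasibility boundary is evaluated on the closed form; the quadrature
  route exists for cross-checking, not production, so both stay available.
- Concentrations carry explicit unit tags (molecules/cm³ vs nM); mixing
  tags raises instead of silently mis-scaling.
- Only the colony-centre concentration is modelled; no spatial maps, no
  time-dependent PDE solution (the steady state is reached on diffusion
  timescales R²/D ≈ minutes, fast against growth timescales of hours).
- The growth model has no lag-phase machinery (no viability states); the
  apparent lag is the small-inoculum transient.
- Problem sizes are small by construction: every packaged computation is a
  handful of closed-form evaluations, one quadrature, or one ODE solve
  over ≤ 481 reported points.
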