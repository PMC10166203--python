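# Methods

`retortsim` simulates the thermal sterilization of a sealed can of viscous
puree in a steam retort, computes the accumulated lethality (F-value) field,
locates the slowest-heating zone (cold point), and scores retort schedules on
the safety/quality trade-off between cold-point sterility and the overheated
(browning-prone) volume.

## Physical model

**Geometry.** A #9121 tin (inner radius 49.45 mm, inner height 121 mm) holds
puree up to 5 mm below the lid; the gap is a vapor headspace.  The model is
two-dimensional axisymmetric in (r, z) with z = 0 at the can bottom.  The
0.2 mm metal wall is treated as thermally transparent: the inner surface takes
the retort temperature directly (Dirichlet).  No wall material data or
external film coefficient is available to justify anything richer; a Robin
film-coefficient boundary (`boundary="robin"`, `film_coefficient` in W/m²K)
is exposed for sensitivity work, and `boundary="insulated"` supports
conservation checks.

**Product.**  The puree is a temperature-dependent Newtonian fluid.  Density,
dynamic viscosity and thermal conductivity are polynomials in absolute
temperature; specific heat is constant at 3860 J/(kg K).  The built-in
`chestnut_puree` set was fitted between 30 and 95 °C and is extrapolated
above (with a logged warning): over the retort range it gives
ρ ≈ 1049–1073 kg/m³, μ ≈ 31–36 Pa·s, k ≈ 0.58–0.61 W/(m K),
α ≈ 1.4·10⁻⁷ m²/s.  Real purees are shear-thinning; no shear-rate dependence
is modelled because no such law is available for this product — see
*Limitations*.

**Headspace.**  Stagnant conductive vapor layer with fixed properties
(k = 0.03 W/(m K), ρ = 0.8 kg/m³, Cp = 2000 J/(kg K), configurable).
Condensation dynamics during cooling are not modelled.  The puree free
surface is a rigid, no-penetration, free-slip lid.

**Flow.**  Buoyant natural convection at μ ~ 30 Pa·s is creeping
(Re ≪ 1, Ra ~ 10³–10⁴), so the momentum equation is solved in Stokes form:
the inertial advection term is dropped, the time derivative uses the
constant reference density ρ(T₀), and buoyancy enters the axial momentum
source as (ρ(T₀) − ρ(T))·g (Boussinesq-type: full temperature-dependent
density in gravity, constant density elsewhere).  Viscosity is the local
μ(T).  The viscous term uses the componentwise diffusion form ∇·(μ∇u) with
the axisymmetric −μu_r/r² curvature sink; the ∇μ·∇uᵀ part of the full
stress divergence is neglected (μ varies by ≲ 2.5× across the can).

**Lethality.**  The lethal rate is L(T) = 10^((T(°C) − RT)/Z) with
RT = 121.1 °C and Z = 10 °C (proteolytic *C. botulinum* reference);
F(r, z) = ∫ L dt in minutes is accumulated every step by trapezoid between
consecutive temperature fields.  The cold point is the puree cell with
minimum accumulated F (ties break toward smallest z, then smallest r).  The
overheated-zone (OZ) fraction is the puree-volume share with F above a
threshold (default 25 min), the proxy used for wall browning.  The
commercial-sterility default target is F₀ = 4.5 min at the cold point.

**Retort schedules.**  Programs use the canning shorthand
`"a-b-…-c/T1-…"`: come-up *a* min, holds *b…* min at the listed °C
set-points, cool *c* min.  Come-up is a linear wall ramp from the initial
product temperature (the retort's own come-up profile is not specified);
cooling is a linear ramp to the cooling-water temperature (default 25 °C);
a step between stacked holds is smoothed over 1 s to keep the boundary
condition continuous.

## Numerics

Finite volumes on a uniform staggered (MAC) grid; default 24×48 cells,
dt = 1 s with automatic halving (up to 2⁶) on a maximum-principle violation.
The headspace boundary snaps to the nearest cell edge and the realized
height is reported.

* **Energy**: backward Euler; conservative fluxes with harmonic-mean face
  conductivity; advection as implicit first-order upwind plus an explicit
  van Leer TVD deferred correction (the cell Péclet number exceeds 1 on the
  default grid, so plain upwind would add numerical diffusion comparable to
  the physical conductivity).  The implicit upwind matrix is an M-matrix,
  which preserves the discrete maximum principle to a 0.5 K tolerance
  enforced at run time.
* **Momentum + continuity**: solved **coupled** each step as one
  saddle-point system (velocity unknowns with the discrete pressure
  gradient; continuity rows with the discrete divergence; one pressure
  value pinned).  A split projection scheme was tried first and rejected:
  with the viscous operator ~10³× stiffer than the time term, the splitting
  error leaves O(10⁻⁴ m/s) spurious currents even in a hydrostatically
  balanced (uniformly buoyant) can, which is the same order as the physical
  flow.  The coupled solve keeps that state quiescent to machine precision
  and holds the volume-weighted RMS divergence near 10⁻¹³ s⁻¹ (tolerance
  10⁻⁶ s⁻¹).
* **Verification oracles** (all in the test suite): a separable
  Fourier–Bessel series for conduction in a finite cylinder (agreement
  within 1 % of the wall step at Fo = 0.1 on 48×96); an analytic two-mode
  Bessel creeping-flow profile for the Stokes operator (≤ 2 % at 24×120);
  exact energy conservation under insulated boundaries; fine-quadrature
  checks of the lethality integral.

Property polynomials are clamped to the valid range inside the solver's
material evaluation (polynomial tails are meaningless there); the property
module itself applies the configured extrapolation policy.

## Synthetic probe data

The probe generator emulates a thermal-penetration test: a thermocouple at
a stated (r, z) — canonically (0, 0.0188 m), the predicted cold point —
recorded through the whole cycle.  The sensor model is a first-order lag
(exact per-interval exponential update, default τ = 5 s) plus i.i.d.
Gaussian read-out noise (default σ = 0.25 K, consistent with the ±0.5 K
initial-fill tolerance read as ~2σ), seeded for reproducibility.  It does
**not** emulate probe-fixture heat-transfer perturbation, radial placement
error, or drift, so a green round-trip test establishes internal
consistency of the simulate → measure → compare → integrate loop, not
agreement with any physical instrument.

## Design choices on open points

* Polynomial temperature argument is kelvin (the only reading that gives
  physically plausible property values; asserted by test).
* The viscosity quintic has a shallow minimum near 391.6 K; it is used
  verbatim, and monotone decrease is only asserted up to 390 K.
* The OZ denominator is the puree volume (headspace excluded).
* The cold-point probe sits on the axis at z = 18.8 mm.
* Conduction-mode cold-point position: with the insulating headspace the
  slowest zone sits near the *top* of the puree; the textbook mid-height
  result is recovered only for a brim-full can with symmetric boundaries
  (both covered by tests).
* The schedule search enumerates candidate grids exhaustively
  (reproducibility over cleverness) and only proposes two-stage programs
  with decreasing temperature sequence, the pattern that narrows the
  F-spread.

## Limitations

* The Newtonian μ(T) abstraction likely **overstates convective stirring**
  for a real shear-thinning puree: at natural-convection shear rates
  (~10⁻² s⁻¹) the apparent viscosity of such products is far above the
  viscometer value, and the true regime is closer to conduction.  The
  package therefore exposes both modes; conduction mode predicts a much
  lower cold-point F and a thinner overheated shell for the same schedule.
  Users fitting real penetration data should treat the mode (or an
  effective viscosity multiplier via a custom property set) as part of
  model calibration.
* Headspace condensation, can rotation, 3-D effects, particulates and
  microbial/nutrient kinetics beyond the single F-integral are out of
  scope.
* First-order-in-time splitting between energy and momentum (the flow
  field lags the temperature by one step); immaterial at dt = 1 s against
  process times of hours.
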