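# Methods

This note records the model assumptions, the numerical choices, and the
design decisions taken where the problem left the design genuinely open.

## Physical model

The package treats a particle-laden flow in a narrow plane gap (height
H ≈ 150 µm, width-to-height ratio ≥ 7 so side walls are ignored) as a
single-phase flow with a prescribed heterogeneous viscosity µ_loc(h, x).
Particle migration is not computed; its net effect — a cell-free layer
(CFL) of pure carrier fluid at each wall and a correspondingly enriched
core — is imposed on the viscosity field.  The fluid is Newtonian: at the
shear rates of these gap flows (order 10²–10⁴ s⁻¹) blood is well past its
shear-thinning range, so only the high-shear asymptotic viscosity enters.

Three streamwise sections:

1. **Homogeneous inlet** (x ≤ x₀, default 1 µm): uniform µ_rheo.  The
   length is an empirical device that seeds the development section; it is
   configurable.
2. **Development** (x₀ < x < x*): per-wall CFL height
   H_CFL(x) = a (x − x₀)^p with p = 0.5 (tilted parabola).  The exponent is
   exposed because the growth law is an empirical closure, not a derived
   result; nothing downstream assumes p = 0.5.  Development is declared
   complete where the relative growth over a step Δx (default 1 µm) drops
   below 0.1 %; whether that threshold is relative or absolute, and over
   which increment, was an open reading — relative per µm was chosen and
   both knobs are parameters.  For the power-law form the criterion has the
   closed-form solution x* = x₀ + Δx / ((1 + tol)^(1/p) − 1).
3. **Steady state** (x ≥ x*): one of two submodels, switching
   instantaneously at x* (a blended transition was considered and rejected
   as an unforced complication; with the step submodel the two sections
   coincide at x* anyway).

At every station the profile obeys two constraints: viscosity equals
µ_carrier inside the CFL bands, and the height average (1/H)∫µ_loc dh
equals the rheometer value µ_rheo — expelled particles do not vanish, they
crowd the core.

**Step submodel.**  Core viscosity from the consistency formula
µ_step = (H µ_rheo − H_cfl µ_carrier)/(H − H_cfl).  H_cfl here is read as
the **total** cell-free thickness (both walls combined): only that reading
makes the two-band profile average exactly to µ_rheo.  A per-wall reading
is available (`convention="per-wall"`) for sensitivity studies; it yields a
higher core viscosity and violates the average constraint, and the
assembly does not silently repair it.

**Local-distribution submodel.**  A fourth-degree polynomial is fitted
(ordinary least squares, `numpy.polynomial`) to the Einstein–Roscoe
viscosity of a measured/synthetic steady particle profile on the core,
floored at µ_carrier if it dips below (with a warning), then the excess
over µ_carrier is rescaled by the unique factor β so the assembled profile
averages to µ_rheo.  β acts on the excess, never on µ itself, so the CFL
bands stay exactly at the carrier viscosity.  β < 1 where the
Einstein–Roscoe closure over-predicts the measured bulk viscosity (blood at
5 %: 1.6434 vs 1.45 mPa·s) and β > 1 where it under-predicts (PEG–water
analog fluid at 5 %: 3.39 vs 5.95 mPa·s).

## Flow solver

Fully developed unidirectional flow with wall-normal viscosity:
d/dh(µ du/dh) = −G, u(0) = u(H) = 0.  Shear stress is linear,
τ(h) = G(h₀ − h), with h₀ = ∫(s/µ)ds / ∫(1/µ)ds; velocity follows by
quadrature and G is scaled to match the prescribed bulk velocity.  Wall
stresses are G·h₀ and G·(H − h₀).

Streamwise variation uses the quasi-developed (lubrication) approximation:
the developed solution is applied to each station's column and
Δp = ∫G(x) dx integrated by the trapezoid rule over the station grid
(section boundaries are stations, so the kinks at x₀ and x* are captured).
Inertial development at the inlet is neglected; the model's viscosity
varies slowly in x and the observables are integrated losses and
steady-section stresses, for which this is the standard thin-gap
approximation.  A full 2-D Navier–Stokes solution is out of scope.

The pressure-loss coefficient is defined as c_p = Δp/(½ρc²); no particular
normalisation is canonical here, and any constant multiple cancels in the
reported ratio c_p/c_p,0% (carrier-only reference at the same Re).  The
Reynolds number uses the gap height H as characteristic length by default
(hydraulic diameter available), and each fluid's own µ_rheo.  Because Re is
matched, c ∝ 1/ρ and the ratio reduces analytically, in the developed
limit, to µ_eff/µ_rheo — independent of density, channel length and Re.
Absolute Δp and τ_w in Pa do depend on the user-supplied density (default
1050 kg/m³, a typical blood-like value) and on the Re length convention,
and are reported with that caveat.

## Discrete representation and numerical choices

* The field is stored as **cell averages** on a uniform wall-normal grid
  (default 256 bins) and treated as piecewise-constant per cell.  Cells
  straddling a CFL edge receive the exact partial-volume average.  Two
  consequences: the height-average constraint holds to machine precision
  at every station with no grid-alignment requirement, and the flow
  solver's per-cell quadratures (1/µ and s/µ moments analytically; the
  in-cell quadratic velocity integrated by in-cell Simpson) are **exact**
  for piecewise-constant viscosity.  Constant-viscosity columns reproduce
  plane-Poiseuille closed forms to ~1e-12 relative, and edge-aligned
  two-layer columns match the core-annular effective-viscosity closed form
  1/µ_eff = (b/a)³/µ_core + (1 − (b/a)³)/µ_CFL to the same level; smooth
  viscosity profiles converge at second order in the bin width (asserted in
  the tests).
* Station grid: 2 inlet stations, 64 in the development section
  (the gradient varies fastest there), 16 in the steady section; all
  configurable via `GridSpec`.
* The assembly refuses grids whose bins do not resolve the steady CFL with
  at least 4 cells, and any configuration whose total CFL reaches the full
  gap height.
* CFL detection threshold ε defaults to 1e-4 absolute volume fraction —
  well below any plateau at φ ≥ 1 % — and detection returns band edges on
  the bin grid, so recovery is exact to one bin width.
* Problem sizes throughout the tests (grids of 100–512 bins, a few dozen
  stations, 100–200 Monte-Carlo replicates) were chosen as the smallest
  sizes at which the asserted tolerances are comfortably met by the
  numerics rather than by slack.

## Synthetic data generator

The generator emulates the *output* of an APTV measurement campaign — a
binned wall-normal concentration profile per streamwise station — not the
optics that produce it.  Features emulated: particle-free bands of
prescribed per-wall thickness; a core that is either a flat plateau or a
mid-plane-peaked quartic bump (particles cluster near the mid-plane; the
quartic shape deliberately gives the polynomial submodel an
exact-recovery pathway); exact mass bookkeeping (noiseless bin-average of
φ equals φ_bulk; no tube-versus-discharge hematocrit correction is
applied, matching the consistency logic used for viscosity); additive
truncated-Gaussian per-bin noise, seeded and bit-reproducible (a
count-based noise model was considered and left out — the plain Gaussian
is the simplest model consistent with binned counting scatter).
Development planes evaluate the growth law at their stations, so feeding
two noiseless planes through detection and calibration closes the loop on
the configured widening coefficient.

What passing tests on this generator do **not** show: real APTV profiles
carry depth-of-correlation bias, wall-proximity detection loss and
non-Gaussian counting noise, and real CFL edges are not sharp.  The
recovery and conservation results certify the pipeline's internal
consistency, not instrument fidelity.

The preset catalog carries the measured rheology pairs (plasma 1.38 /
blood 5 % 1.45 mPa·s; analog carrier 2.85 / analog 5 % 5.95 mPa·s; a
hypothetical 45 % hematocrit at 3.63 mPa·s) and the observed 20 µm
steady CFL for the analog fluid in the 150 µm gap.  The calibration-plane
stations in the presets (401 and 1601 µm) are synthetic placeholders
consistent with a = 0.5 µm^½ and the 20 µm steady height; measured plane
coordinates are not available.

## Known limitations

* Validity envelope: gap heights ≈ 150 µm, φ ≤ 5 %, Re ≈ 50–150.  The
  Einstein–Roscoe closure is known to fail at physiological hematocrits;
  the adjustment factor absorbs modest closure error but is not a
  substitute for a high-φ rheology law, which is deliberately not
  implemented.  Above φ = 5 % the fluid spec warns rather than errors,
  since the machinery itself remains valid for analog fluids at higher
  loadings.
* The CFL is prescribed, not predicted: steady heights come from
  measurement, fixture or configuration; there is no lift-force model, and
  no coupling from the solved shear field back to migration.
* The quasi-developed march has no entrance-region inertia; reported Δp is
  a lower-order estimate wherever the true flow is still developing
  hydrodynamically (distinct from the particle-migration development the
  model does represent).
* Reported c_p ratios for blood sit close to the analytic lower bound
  µ_carrier/µ_rheo = 0.9517 regardless of CFL height (the whole admissible
  range is (0.9517, 1)); conclusions about the blood CFL height drawn from
  c_p ratios alone are therefore weakly identified, and the solver exposes
  the height as a free parameter rather than asserting one.
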