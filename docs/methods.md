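# Methods

## Scope and model chain

`cornesim` couples four components in the order the physics runs:

1. **GAB sorption equilibrium** — water activity `aw` to sorbed volume `V`,
   concentration `Cw` and swollen thickness `delta`.  Constants: `c = 4.39`,
   `k = 1/1.01`, `Vm = 0.0386` g/g, `rho_w = 1.0`, `rho_mem = 1.3` g/cm^3,
   `delta_dry = 9.55` um.  The chain is strictly monotone below the isotherm
   pole (`k aw = 1`, i.e. `aw ~ 1.01`), so the inverse map concentration →
   activity is a bracketed root-find accurate to ~1e-15.
2. **Moving-boundary water transport** through the SC slab.
3. **Hydration-dependent dielectrics** for the SC plus fixed Cole–Cole sets
   for epidermis/dermis (blood-like) and hypodermis (infiltrated fat).
4. **Quasi-static complex-conduction FEM** producing admittance, capacitance,
   conductance and current-density fields per electrode geometry.

The skin model used by the field solver deliberately carries *no* water
concentration gradient: each hydration level enters as one bulk `Cw` for the
whole SC (the transport model supplies the physiological range of such
levels).  Coupling a depth profile into the dielectric layer is out of scope.

## Transport model

State: concentration profile `Cw(xi)` on the normalized depth coordinate
`xi = z/delta(t)` (front-fixing/Landau transformation), plus the thickness
`delta`.  Equations, all CGS:

* interior: `dCw/dt = -v dCw/dz + d/dz (D(Cw) dCw/dz)` with the convective
  velocity `v = f0/rho_w` driven by the lower-boundary flux `f0`;
* diffusivity `D(Cw) = 0.433 (1 - 0.3765 e^{-9.6215 Cw}
  + 6.428e-5 e^{12.873 Cw}) x 1e-9 cm^2/s` (2.7e-10 dry, ~1.1e-9 fully
  hydrated).  The printed source formula is typographically flattened; this
  reading and the alternative (`0.433 - 0.3765 e^{...} + ...`) are both
  available behind `SorptionModel.d_reading`, with the parenthesized form the
  default (it reproduces the dry-end literature value 2.7e-10 cm^2/s);
* lower boundary (epidermal junction): Dirichlet `Cw = 0.781 g/cm^3`;
  `f0` follows algebraically from the flux definition
  `f = -D dCw/dz + v Cw` with `v = f0/rho_w`:
  `f0 = -D dCw/dz|_0 / (1 - Cw(0)/rho_w)`;
* surface: evaporative (TEWL) Robin condition
  `f_delta = kg (aw(Cw_surf) - RH) p_sat MW/(R T)` with `kg = 0.318 cm/s`,
  `p_sat = 4.76 kPa`, `T = 305.2 K`, and the gas constant expressed as
  8.314e6 cm^3 Pa/(K mol) so the flux comes out in g/(cm^2 s);
* boundary motion: `d delta/dt = (f0 - f_delta)/rho_w`.

Discretization: 101 nodes graded toward the surface (`xi = 1 - (1-u)^2.5`),
conservative finite volumes for diffusion, central advection, a 3-point
one-sided inner gradient.  `step_transport` performs one adaptive
backward-Euler step (damped Newton, dt halving on rejection);
`run_to_equilibrium`/`run_protocol` integrate the identical right-hand side
with SciPy's variable-order BDF and the sparse Jacobian pattern, checking the
equilibrium tolerances (`max|dCw/dt| < 1e-9 g/(cm^3 s)`,
`|d delta/dt| < 1e-8 um/s`) on geometrically growing windows up to
`t_max = 1e6 s`.

### Behaviour of the printed model, and what we report

Two properties of this equation set matter for interpreting results:

* **The surface node equilibrates near ambient.**  With the printed transport
  constants the evaporation coefficient (`kg rho_vap ~ 1.1e-5 g cm^-2 s^-1`
  per unit activity difference) outruns diffusive resupply
  (`D/delta ~ 2e-7 cm/s`) by orders of magnitude, so the *surface* activity
  settles a few percent above ambient RH.  The physiological "SC water
  concentration" of a state is therefore reported as the **depth-averaged**
  (bulk) concentration of the converged profile, which is the quantity the
  hydration-dependent dielectric model consumes.  At RH = 0 the bulk value is
  0.546 g/cm^3 (activity 0.968) and at RH = 1 it is 0.789 g/cm^3 (0.996) —
  close to, but ~7 % below, the published dry-air figure of
  0.585 g/cm^3/0.9745.  No reading of the diffusivity or flux units that we
  examined moves the surface node to the published value at a true steady
  state; the bulk average is the self-consistent interpretation, and the
  residual offset is documented rather than calibrated away.
* **Thickness creeps on drying branches.**  The thickness law is a water
  volume balance, not a dry-mass conservation law.  Once the surface has
  dried, the fixed inner concentration keeps feeding water to the slab
  (`f0 > f_delta` persistently), so `delta` grows slowly without bound while
  the concentration statistics converge.  `run_to_equilibrium` consequently
  reports `converged = False` on drying branches (the thickness-rate
  tolerance is never met) while the concentration values it returns are
  stable to <0.1 %.  `dry_mass_per_area` exposes the dry-matrix drift as a
  diagnostic; the physics is implemented as printed, not "fixed".

The fixed point of the dynamics is uniform `Cw = 0.781` at
`RH = aw(0.781) = 0.9959` (not exactly RH = 1, where slight condensation
occurs); the property tests use the self-consistent value.

## Dielectric models

Complex permittivity convention `eps = eps' - j eps''` with `e^{+jwt}`.
SC: two Debye terms (free water, protein polarization) with increments and
relaxation times proportional to `Cw` in kg/m^3 — shipped scalings
0.0557, 1.551e-14 s, 0.432, 1.785e-11 s per (kg/m^3) — plus
`eps_inf = 3.3 + (2/73.2) d_eps_free` (dry protein 3.3; 73.2 is the static
permittivity of free water; the printed source expression is a flattened
fraction, and the alternative readings differ by <2 permittivity units at
full hydration).  The shipped scalings are used downstream everywhere;
`fit_beta` re-derives such scalings by through-origin least squares.  Our own
protocol snapshots (30-minute exposures at RH 40/60/80 % starting from the
30 %-RH state) land at bulk concentrations of ~556/559/568 kg/m^3 and
reproduce the published free-water scaling to ~7 %, consistent with the bulk
offset noted above.

E/D and hypodermis use fixed literature Cole–Cole sets (sigma_dc 0.7 and
0.035 S/m).  Bound-water dispersion and temperature dependence are omitted.

## Field problem

`div(sigma* grad V) = 0`, `sigma*(f) = j w eps0 eps_r(f)` (DC conductivity
rides inside `eps_r`); electrodes are infinitely thin equipotential segments
at ±V/2 (drive amplitude 1 V; the problem is linear), all other boundaries
insulating.  P1 triangles on structured tensor meshes of right triangles
(never obtuse, which keeps the discrete admittance passive), graded toward
electrode edges where the current density is singular.  The circular
electrode is solved in axisymmetric (r, z) with 2*pi*r weighting; the
interdigitated electrodes as a planar (x, z) cross-section whose per-length
admittance is scaled by the finger length.  Admittance comes from the
Dirichlet reaction (the consistent discrete boundary current); the
unconjugated energy functional is computed as a cross-check and agrees to
machine precision.  Closed-form fixtures (parallel plate, coaxial cylinder)
validate C and G to better than 0.1 %.

Defaults where the source material prints none, chosen once as realistic:
5 fingers per electrode of length 5 mm (sensitivity ratios are
finger-length-independent in the planar approximation); a 25-um polyimide-like
insulation film (eps_r = 3.4) for the capacitance electrode; lateral domain
extent 12 mm, validated by the 1 %-boundary-influence rule
(`ensure_domain_size` grows the extent by 1.5x until the capacitance moves
<1 %).  Mesh densities are set so that one refinement level (a >2x point
increase, which at least halves edge spacing near electrode edges) changes
the capacitance of every default electrode by <2 % (~1 % for the circular
one); refinement level 1 is used for the study tables.

## Studies and summary statistics

* **Hydration range**: staged humidity protocol — dehydrate fully hydrated
  tissue at RH 30 % until settled, then expose that state to RH 0 %/100 %;
  report bulk concentration and activity of both extremes.
* **Thickness influence**: C(aw) at 1 MHz on the activity grid
  {0.80, 0.85, 0.90, 0.925, 0.95, 0.97, 0.985, 0.996} (refined near the
  turning point), swelling vs constant 9.55 um.  With swelling the peak sits
  at aw = 0.95 (circular) / 0.97 (interdigitated); constant thickness is
  monotone.  The peak persists from 10 kHz to 1 GHz.
* **Dimension sensitivity**: r(aw) per swept dimension.  A geometry's scalar
  sensitivity is the peak-to-peak span of r over the hydration range: r
  crosses zero just below the turning point, so |r| at any single activity is
  monotone in the gap and blind to the overall response swing.  The
  interdigitated-conductance gap sweep peaks interior at d ~ 0.145 mm
  (quadratic interpolation through the three best grid points; the span is
  flat to 0.1 % over 0.10–0.18 mm, so the location carries ~±0.02 mm of
  numerical uncertainty).  The published optimum is ~0.12 mm.
* **Family comparison**: conductance- vs capacitance-electrode sensitivity
  compared by the ratio of peak |r| magnitudes below aw = 0.95 (~79x circular,
  ~102x interdigitated) — the pointwise ratio is kept as a diagnostic but is
  dominated by the zero crossing of r near aw ~ 0.9.  The absolute
  capacitance-electrode sensitivity depends on the insulation film, whose
  exact material/thickness is a documented geometric uncertainty; ratios this
  large are insensitive to that choice in sign and order of magnitude.

## Known limitations

* Absolute capacitance magnitudes are not validated against published figure
  axes (not a permitted numeric source); monotonicity, turning point and
  ratio properties stand in for them.
* The dry-air bulk concentration sits ~7 % below the published 0.585 g/cm^3
  and the 30-minute snapshots correspondingly ~6 % below the published
  regression support points; the activity scale compresses this to <1 %.
* 2D cross-section for interdigitated electrodes (no 3D end effects), no
  electrode–skin contact impedance, no sweating/occlusion/damaged-skin
  scenarios, no bound-water dispersion.
* Passing tests demonstrate internal consistency of this model chain, not
  agreement with in-vivo measurements: the synthetic study conditions assume
  homogeneous layers, a fixed epidermal water supply, and equilibrium
  sorption at the surface.
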