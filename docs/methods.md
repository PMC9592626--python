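# Methods

## The physical model

A single well of a polystyrene 24-well plate holds a cylindrical water
column (radius r = 7.950 mm, height H = 10.78 mm) and sits on a planar
1 MHz ultrasound transducer, coupled through the 1.3 mm polystyrene base.
The package solves the time-harmonic (frequency-domain) acoustics of that
column:

```
div( -(1/ρ_c) ∇p ) - k_eq² p / ρ_c = 0
```

with the complex (lossy-fluid) material model

- sound diffusivity   δ = (4/3·μ + μ_b)/ρ,
- complex sound speed c_c = c·(1 + iωδ/c²)^½,
- complex density     ρ_c = ρc²/c_c²,
- wavenumber          k_eq = ω/c_c.

Boundary conditions (outward normal n):

- lateral wall: impedance condition with the polystyrene impedance
  Z_ps = 2.5·10⁶ Pa·s/m — flux `n·((1/ρ_c)∇p) = -iωp/Z_ps`;
- top (water/air) surface: same form with Z_air = 401.7 Pa·s/m, which is
  nearly pressure-release (Z_air ≪ ρc);
- bottom: prescribed normal displacement of amplitude L_D — flux
  `n·((1/ρ_c)∇p) = (iω)²L_D`;
- axis: no condition; the axisymmetric weak form is naturally regular.

The drive amplitude comes from the transducer input power density
I_input through two closed forms: the exponential attenuation of the
well base, `I_0 = I_input·e^(-2αt)` with α = 0.108 cm⁻¹ and t = 1.3 mm,
and the plane-wave displacement relation `I_0 = ½ρcω²L_D²`, giving
`L_D = sqrt(2I_0/(ρcω²))`. For the three study powers 0.30 / 0.45 /
0.60 W/cm² this yields L_D = 9.945 / 12.181 / 14.065 nm.

Modelling assumptions: fixed temperature (298.15 K properties), linear
acoustics (no cavitation-bubble dynamics, no streaming, no thermal
coupling), no sources inside the fluid (monopole and dipole volume
sources identically zero), and the well base entering only through the
attenuation factor and the wall impedance — it is not modelled as an
elastic layer.

## Time convention and signs

All phasors carry `e^{+iωt}`. Consequences, fixed once and used
everywhere: the impedance flux is `-iωp/Z`; the particle velocity is
`v = -∇p/(iωρ_c)`; the time-averaged intensity is `I = ½Re(p·v*)`; and
with the principal square-root branch Im(k_eq) < 0, so the outgoing wave
`e^{-ik_eq z}` decays in its propagation direction (the same physics is
written Im(k) > 0 under the `e^{-iωt}` convention).

## Discretization

The geometry, loading and boundary conditions are all axisymmetric, so
the problem is solved on the meridian rectangle [0, r] × [0, H] with the
area element ∝ ρ_r, which is exact — not an approximation of a 3-D
solve. The grid is uniform, with tensor-product Lagrange elements:

- **Element size.** h ≤ λ/8 with λ = c/f (the 8–10 elements-per-wavelength
  rule for FEM acoustics); the coarsest admissible grid is the default
  (`refinement=1`, h = 0.185 mm at 1 MHz). `refinement=k` multiplies the
  base element counts by k, so integer refinements nest exactly.
- **Element order.** Quadratic (Q2) by default. Cubic (Q3) elements on
  the same grid are available and are used for validation studies: at
  refinement 2 the Q2 basis retains a dispersion-driven error of ~0.2%
  against the closed-form column solution (the nearly closed column is
  close to resonance, which amplifies small phase errors into amplitude
  errors), while Q3 reduces it to ~6·10⁻⁶.
- **Quadrature.** (order+2)-point Gauss per direction, which integrates
  the ρ-weighted element integrands exactly on the uniform grid.
- **Boundary terms.** The impedance and displacement conditions enter as
  natural (Robin/Neumann) boundary integrals with their exact
  coefficients; nothing is lumped. The bottom load is
  `b_a = -ω²L_D ∫ N_a ρ ds`.
- **Linear solve.** Sparse direct factorization (SuperLU) of the complex
  system (~10⁴ unknowns at refinement 1); the relative residual is
  recorded on the returned field (~10⁻¹⁴). Singular factorizations and
  non-finite solutions raise a dedicated error.

Because the discrete problem is linear in L_D, nodal pressures scale
exactly as L_D (∝ √I_input) and intensities as L_D² (∝ I_input); this is
asserted to machine precision in the tests, and implies the exact 1.5 /
√1.5 cross-power ratios seen in the reported averages.

## Reported quantities

- **Pressure amplitude** |p| (reported in MPa).
- **"Acoustic density"** is interpreted as the magnitude of the
  time-averaged intensity vector |½Re(p·v*)| (reported in W/cm²) — the
  standard frequency-domain plot quantity with those units. The
  plane-wave-equivalent intensity |p|²/(2ρc) is also exposed
  (`IntensityField.plane_wave_equivalent`) for comparison; the
  intensity-vector magnitude is the default and reproduces the reference
  table to ~1%, supporting the interpretation.
- **Plane averages.** Vertical planes (x = 0, x = r/2, and 0.1 µm inside
  the wall) are planar sections averaged with uniform (y, z) weighting;
  horizontal planes (z = 0, 2.5, 7.5, 10.7 mm) are disk averages with the
  polar area element; the volume average uses the ρ-weighted volume
  element. Quadrature is a fixed Gauss–Legendre tensor grid, 320 points
  per direction by default (several points per element); doubling the
  resolution changes the averages by <0.1% and is asserted as a
  self-check, and all averages are cross-checked against a seeded
  rejection-sampling Monte-Carlo oracle (10⁶ points, 3-SE band).
- **Extrema.** Instantaneous-pressure extrema are max/min of Re(p) at the
  source phase where the bottom displacement is real and positive; peaks
  of |I| and Re(p) are searched on a dense uniform 500×500 sampling grid.
  Peak values of a standing-wave field are inherently grid-sensitive at
  the percent level; the grid is part of the definition.

## Validation strategy

1. **1-D column oracle.** With a sound-hard lateral wall the exact
   solution is the radially uniform two-wave column
   `p = A·e^{-ikz} + B·e^{+ikz}` fixed by the bottom-displacement and
   top-impedance conditions. The closed form is itself verified against a
   brute-force 200 000-point finite-difference solve (<10⁻⁶ relative
   error), then the FEM with the lateral impedance term removed is
   compared with it nodewise: 6·10⁻⁶ relative L2 at refinement 2 with
   cubic elements (0.23% with quadratic — pure dispersion, documented
   above). This exercises every term of the assembly except the lateral
   impedance matrix, which has the same code path as the top one.
2. **Energy balance.** Input power through the driven base is compared
   with the power leaving through the impedance walls plus the volumetric
   viscous dissipation `D = δ|∇p|²/(2ρc²)`. All terms are measured from
   the recovered field; computing wall fluxes from the boundary data
   (|p|²/2Z) instead would close the balance identically for any Galerkin
   solution and check nothing. The measured imbalance is 3.9% at
   refinement 1, 1.1% at refinement 2 (quadratic), 0.03% at refinement 2
   (cubic) — shrinking discretization error, as required.
3. **Mesh convergence.** Plane averages are Cauchy in refinement;
   refinement 2 → 3 changes are <0.2%. The λ/8 production grid sits ~3%
   below the converged central-plane intensity average (and ~2% on the
   central |p| average) — an accepted discretization offset comparable to
   the quantity-definition uncertainty, and well inside the 10%
   reproduction band used for the reference table.
4. **Closed-form limits.** Lossless reductions (c_c = c, ρ_c = ρ),
   rigid-cap antinodes, matched-impedance travelling waves (|I| = I_0 at
   the base within 0.1%), and the identity ρ_c·c_c² = ρc² (property-based
   test over admissible parameters).

## SCL quantification conventions

Background subtraction is per-pixel with negative differences clamped to
0 (8-bit images cannot represent negatives; this mirrors standard image
calculators — and makes repeated subtraction intentionally
non-idempotent, which is asserted in tests). ROI membership is a
pixel-center test. Automatic ROI detection uses the centroid of
above-threshold blue pixels with radius √2 × their RMS distance (exact
for a uniformly lit disk); a manual ROI always overrides detection. Only
the blue channel is averaged (luminol emits at ~430 nm); red and green
are kept for diagnostics. I_SCL is raw 8-bit counts — no radiometric
calibration is attempted, matching the qualitative use of SCL.

## Synthetic SCL scenes

The generator emulates a dark-room long-exposure pair: a background frame
(per-channel offset + truncated additive Gaussian sensor noise) and a
signal frame adding a circular blue glow with radial profile
`A·(1-(s/R)²)^γ` (γ = 0.5 by default; γ = 0 is a flat disk; defaults:
160×120 px, R = 40 px, A = 120 counts, offsets (3, 3, 6), noise σ = 2).
Ground truth is the pre-noise analytic ROI mean; recovery is asserted
within 3 standard errors (√2·σ/√n, two noise realizations). Everything is
reproducible bitwise from the seed.

What the generator does *not* model — and therefore what passing tests do
not show: luminol reaction kinetics, any mapping from acoustic intensity
to photon yield (no such model exists in the underlying study; emission
amplitude is a free parameter, not a prediction), lens vignetting,
glare/reflections from the well rim, RAW sensor response, or saturation
(generation into saturation requires an explicit flag). Tests prove the
quantifier recovers known emission statistics from realistic noise; they
say nothing about absolute radical yields in real photographs.

## Parameters that matter

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| ρ, μ, μ_b, c | 998, 0.890·10⁻³, 2.485·10⁻³, 1497 | kg/m³, Pa·s, Pa·s, m/s | water at 298.15 K |
| Z_ps, Z_air | 2.5·10⁶, 401.7 | Pa·s/m | wall impedances |
| r, H, t | 7.950, 10.78, 1.3 | mm | well radius, solution height, base thickness |
| f | 1.0 | MHz | drive frequency (continuous wave) |
| I_input | 0.30 / 0.45 / 0.60 | W/cm² | transducer power densities of the study |
| α | 0.108 | cm⁻¹ | polystyrene attenuation coefficient |
| refinement | 1 | — | divides the λ/8 element-size cap |
| element order | 2 | — | 3 available for validation studies |
| averaging resolution | 320 | points/direction | Gauss–Legendre plane quadrature |

## Known limitations

- Single-frequency, linear, lossy-fluid model: no cavitation dynamics,
  no nonlinear propagation, no acoustic streaming, no heating — the model
  predicts the *linear* field that drives those phenomena, not the
  phenomena themselves.
- The polystyrene base and walls are impedance surfaces; structural
  resonances of the plate are outside the model.
- Peak (as opposed to averaged) field values depend on the sampling grid
  and discretization at the few-percent level.
- The impedance condition uses a single real Z per surface; frequency- or
  angle-dependent wall admittance is not modelled.
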