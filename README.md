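# sonowell

Frequency-domain acoustic modelling of a sonicated multiwell-plate well,
with the post-processing used in ultrasound exposimetry and a
sonochemiluminescence (SCL) image quantifier.

## The problem

In vitro sonodynamic-therapy experiments insonate cells or luminol
solutions in a single well of a polystyrene 24-well plate placed on a
planar 1 MHz transducer. The acoustic dose a sample actually receives is
*not* the transducer's nominal power density: the wave is attenuated by
the well base, reflected by the water/air surface and the polystyrene
walls, and focused by the cylindrical geometry into a strongly
non-uniform standing-wave field. `sonowell` computes that field and the
quantities used to report it, for anyone designing or interpreting
well-plate insonation experiments (therapeutic-ultrasound labs,
cavitation dosimetry, sonochemistry).

## The model

The water column (radius r = 7.95 mm, height H = 10.78 mm) obeys the
lossy Helmholtz equation

∇·(−(1/ρ_c)∇p) − k_eq²p/ρ_c = 0,  k_eq = ω/c_c,  c_c = c(1 + iωδ/c²)^½,
ρ_c = ρc²/c_c²,  δ = (4/3·μ + μ_b)/ρ,

with impedance conditions on the lateral wall (Z_ps = 2.5·10⁶ Pa·s/m)
and the top surface (Z_air = 401.7 Pa·s/m), and a prescribed normal
displacement of the bottom wall with amplitude

L_D = √(2I₀/(ρcω²)),  I₀ = I_input·e^(−2αt),

where α = 0.108 cm⁻¹ and t = 1.3 mm describe one-way transmission
through the polystyrene base. The problem is solved exactly in
axisymmetric form with quadratic (optionally cubic) Lagrange finite
elements on a λ/8 grid, and post-processed into pressure-amplitude |p|
and time-averaged intensity |½Re(p·v̄)| averages over reporting planes.
See `docs/methods.md` for conventions, validation and limitations.

The SCL module implements the standard quantification of luminol
photographs: pixel-by-pixel background subtraction (clamped at zero),
circular ROI selection (manual or detected), and the spatial average of
the blue channel, I_SCL, in raw 8-bit counts.

## Worked example

Derived drive quantities at 0.45 W/cm² (`sonowell params --power 0.45`):

```
                                                  value
sound_diffusivity_m2_s                  3.679024716e-06
complex_sound_speed_m_s            1497+0.007720772893j
complex_density_kg_m3        997.9999999-0.01029436386j
wavenumber_1_m               4197.184574-0.02164696652j
angular_frequency_rad_s                     6283185.307
transmitted_intensity_W_cm2                0.4375397605
displacement_amplitude_nm                   12.18057306
```

97.2% of the input intensity survives the base (0.4375 of 0.45 W/cm²),
and the bottom wall oscillates with a 12.18 nm amplitude. Solving and
summarizing the field:

```python
import sonowell as sw

fx = sw.fixtures()                      # the three study drive levels
field = sw.simulate(fx.drives[1])       # 0.45 W/cm^2, lambda/8 mesh
summary = sw.summarize(field, sw.intensity(field), fx.geometry)
print(summary.to_frame().to_string())
```

```
                                   0.45 W/cm2
density_avg_central_W_per_cm2        0.614465
density_avg_half_radius_W_per_cm2    0.287312
density_avg_wall_W_per_cm2           0.105526
density_avg_volume_W_per_cm2         0.351357
pressure_ampl_avg_central_MPa        0.186411
pressure_ampl_avg_half_radius_MPa    0.153893
pressure_ampl_avg_wall_MPa           0.052092
pressure_ampl_avg_volume_MPa         0.151926
peak_density_W_per_cm2               4.929377
max_pressure_MPa                     0.529706
min_pressure_MPa                    -0.565647
```

Reading the table: the acoustic intensity averaged over the central
vertical plane (0.61 W/cm²) *exceeds* the transducer's 0.45 W/cm²
because the cylindrical well focuses the field onto its axis (peak
4.9 W/cm²), while the average over the whole solution volume
(0.35 W/cm²) is lower — energy concentrates centrally and decays toward
the walls (0.11 W/cm² near the wall). Pressure-amplitude averages follow
the same radial decrease; the instantaneous pressure swings roughly
±0.55 MPa. Doubling the input power doubles every intensity entry and
scales pressures by √2 exactly (the model is linear in L_D).

Other entry points: `sonowell solve` (field export to CSV/VTK and plane
maps), `sonowell summarize --powers 0.3,0.45,0.6` (the full cross-power
table), `sonowell synth` (synthetic SCL photograph pairs with ground
truth) and `sonowell scl` (photograph quantification). All accept a YAML
configuration (schema in `sonowell/config.py`).

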