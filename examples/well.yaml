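# Reference configuration: water-filled well of a polystyrene 24-well
# plate on a 1 MHz planar transducer. All values are the package defaults;
# edit any subset — omitted keys fall back to these values.
medium:
  density_kg_m3: 998.0
  dynamic_viscosity_mpa_s: 0.890
  bulk_viscosity_mpa_s: 2.485
  sound_speed_m_s: 1497.0
geometry:
  basis_radius_mm: 7.950
  solution_height_mm: 10.78
  base_thickness_mm: 1.3
impedances:
  lateral_pa_s_m: 2.5e+6
  top_pa_s_m: 4.017e+2
drive:
  frequency_mhz: 1.0
  input_power_w_cm2: 0.45
  attenuation_per_cm: 0.108
solver:
  refinement: 1.0
  lateral_condition: impedance
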