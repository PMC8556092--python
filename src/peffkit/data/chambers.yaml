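# Bundled ionization-chamber records.
#
# The PTW 34080 window is recorded as its PMMA-equivalent stack
# (0.62 mm wall + 1.16 mm electrode PMMA, graphite coat absorbed into the
# electrode thickness), which is the stack whose WET the manufacturer-style
# worked calculation yields (2.0648 mm).  The 34070 window keeps lacquer and
# graphite as separate layers (WET 4.022 mm).  The Farmer 30013 wall layers
# sum to 0.5509 mm WET.
ptw_34080:
  kind: plane_parallel
  active_volume_cm3: 10.5
  pom_convention: "inside of entrance window, center"
  pom_offset_mm: 0.0
  window_layers:
    - {material: pmma, thickness_mm: 0.62}
    - {material: pmma, thickness_mm: 1.16}
ptw_34070:
  kind: plane_parallel
  active_volume_cm3: 10.5
  pom_convention: "inside of entrance window, center"
  pom_offset_mm: 0.0
  window_layers:
    - {material: pmma, thickness_mm: 3.35}
    - {material: graphite, thickness_mm: 0.02, density_g_cm3: 1.85}
    - {material: lacquer, thickness_mm: 0.1}
ptw_30013:
  kind: cylindrical
  inner_radius_mm: 3.05
  active_volume_cm3: 0.6
  pom_convention: "on detector axis, 13 mm behind the tip"
  pom_offset_mm: 13.0
  window_layers:
    - {material: pmma, thickness_mm: 0.335, density_g_cm3: 1.19}
    - {material: graphite, thickness_mm: 0.09, density_g_cm3: 1.85}
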