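# Example run configuration: 0.30% collagen hydrogel, compressible
# Neo-Hookean skeleton (NH2), ramp-hold confined compression with 5%
# strain applied over 10 s and held for 290 s on a 5 mm drainage path.
material: c030
protocol:
  label: "ramp-hold 5% / 10 s (cylinder, H = 5 mm)"
  strain: 0.05
  ramp_s: 10.0
  hold_s: 290.0
  height_mm: 5.0
variant: NH2
solver:
  n_elements: 100
  newton_tol: 1.0e-9
output_prefix: busby_c030_nh2
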