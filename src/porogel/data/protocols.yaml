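# Ramp-hold confined-compression loading protocols.
# busby: cylindrical samples, radius 8 mm, height 5 mm; 5% compression
#        applied over 10 s, then held for 290 s.  Drainage path = 5 mm.
# chandran: cuboid samples 3 x 3 x 15 mm; 10% compression over 100 s, held
#        for 2000 s.  The 15 mm dimension is taken as the loading/drainage
#        axis: with the 0.30% gel parameters the consolidation time constant
#        H^2/(HA k0) is ~1.9e3 s for H = 15 mm, consistent with the 2000 s
#        relaxation window, versus ~75 s for H = 3 mm.
busby:
  label: "ramp-hold 5% / 10 s (cylinder, H = 5 mm)"
  strain: 0.05
  ramp_s: 10.0
  hold_s: 290.0
  height_mm: 5.0
chandran:
  label: "ramp-hold 10% / 100 s (cuboid, H = 15 mm)"
  strain: 0.10
  ramp_s: 100.0
  hold_s: 2000.0
  height_mm: 15.0
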