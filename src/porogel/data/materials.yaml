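# Constitutive parameter sets for collagen hydrogels at three collagen
# concentrations (% by weight), as used throughout the simulation campaign.
# Units are explicit in the key names: moduli in kPa, compressibility D1 in
# 1/kPa, zero-strain hydraulic permeability k0 in m^4/(N s) == m^2/(Pa s).
# All sets use a drained Poisson's ratio of 0.2, so K = 2G(1+nu)/(3(1-2nu))
# and C10 = G/2, D1 = 2/K hold at the printed precision.
c020:
  label: "collagen 0.20%"
  G_kPa: 0.3375
  C10_kPa: 0.1688
  K_kPa: 0.4500
  D1_per_kPa: 4.444
  k0_m4_per_Ns: 1.70e-10
  M: 1.8
  nu: 0.2
c030:
  label: "collagen 0.30%"
  G_kPa: 0.3750
  C10_kPa: 0.1875
  K_kPa: 0.5000
  D1_per_kPa: 4.000
  k0_m4_per_Ns: 1.20e-10
  M: 2.1
  nu: 0.2
c040:
  label: "collagen 0.40%"
  G_kPa: 0.4500
  C10_kPa: 0.2250
  K_kPa: 0.6000
  D1_per_kPa: 3.333
  k0_m4_per_Ns: 0.80e-10
  M: 3.5
  nu: 0.2
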