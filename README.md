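# porogel

Finite-strain poroelastic consolidation modelling of highly hydrated
collagen hydrogels.

Collagen gels used as tissue-engineering scaffolds are >99% water: under
compression they behave as biphasic (poroelastic) media in which the total
axial stress splits into the drained skeleton's effective stress and the
pore fluid pressure, σ_zz = σᵉ_zz(λ) − p.  In a confined-compression
stress-relaxation test the sample is compressed between rigid impermeable
lateral walls and an impermeable bottom platen, with drainage only through
the loaded top face; the displacement is ramped to a fixed compressive
strain and held while the pore pressure dissipates and the stress relaxes
toward the drained equilibrium.

`porogel` implements this configuration as a one-dimensional finite-strain
u–p consolidation solver on the material frame, with

* **three Neo-Hookean skeleton variants** —
  NH1, the incompressible-form energy W = C₁₀(I₁ − 3) completed with a
  −2C₁₀ ln J term so the reference state is stress-free;
  NH2, the compressible form W = G/2 (I₁ − 3) − G ln J + (K − 2G/3)/2 (ln J)²
  in shear and bulk moduli; and
  NH3, the generic-compressibility form W = C₁₀(Ī₁ − 3) + (1/D₁)(J − 1)²
  on the isochoric first invariant;
* **strain-dependent permeability** (van der Voet law) k(J) = k₀ Jᴹ, so
  compaction throttles drainage;
* bundled **material parameter sets** for 0.20 / 0.30 / 0.40 % collagen
  concentration (C₁₀ = G/2, K = 2G(1+ν)/(3(1−2ν)) at ν = 0.2, D₁ = 2/K)
  and the two **ramp-hold protocols** used to characterise them
  (5 % strain in 10 s + 290 s hold on a 5 mm drainage path; 10 % strain in
  100 s + 2000 s hold on a 15 mm path);
* a classical **linear consolidation oracle** (Terzaghi step-load series and
  the displacement-controlled ramp-hold series) used to verify the
  nonlinear solver in its small-strain, constant-permeability limit;
* an **experiment suite** that runs the full 12-simulation campaign
  (4 protocol × material cells × 3 variants) and reports symmetric percent
  differences between the variants' peak and end-of-hold effective
  stresses.

The solver discretises mass balance ∂λ/∂t = ∂/∂Z [k_eff(λ) ∂p/∂Z] with
finite volumes and backward-Euler/Newton stepping, eliminating the pressure
through the uniform-total-stress momentum balance; the scheme conserves
fluid volume exactly and the total stress is uniform by construction.

## Worked example

Simulate the 0.30 % gel under the 5 %/10 s ramp-hold protocol with the
compressible Neo-Hookean skeleton:

```bash
$ porogel simulate --material c030 --variant nh2 --protocol busby --out run
wrote run.csv and run.summary.json
peak effective stress 0.3091 kPa, end-of-hold 0.0520 kPa
```

The peak (0.309 kPa, reached at the end of the 10 s ramp) exceeds the
drained equilibrium because the ramp is fast compared with the
consolidation time constant H²/(Hₐ k₀) ≈ 208 s, so most of the load is
initially carried by pore pressure.  Over the 290 s hold the stress relaxes
toward the drained value; the end-of-hold 0.052 kPa matches the closed-form
skeleton stress σᵉ(λ = 0.95) = 51.99 Pa of the NH2 energy to within the
residual pressure.  `run.csv` holds the full time series
(`time_s,sigma_total_kPa,p_bottom_kPa,sigma_eff_bottom_kPa,outflow_mm`,
compressive stresses positive).

The same quantities from the library:

```python
import porogel as pg
from porogel.config import load_protocol_blocks

c030 = pg.table1_materials()[1]
busby = load_protocol_blocks()["busby"]
history = pg.simulate(c030, "NH2", busby)
print(history.peak_effective, history.end_effective)  # Pa: 309.1, 51.99
```

Other entry points: `porogel materials` prints the bundled parameter sets
with their derivation checks, `porogel oracle` writes the linear analytic
solution in the same CSV schema, and `porogel suite` runs the full
comparison campaign (per-run CSVs, `comparison.csv`, `differences.json`).

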