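# Methods

## Model

A saturated collagen hydrogel is treated as a biphasic mixture of an
intrinsically incompressible hyperelastic skeleton and an intrinsically
incompressible pore fluid.  In confined compression the kinematics are
uniaxial: with material coordinate Z ∈ [0, H] (Z = 0 the impermeable bottom,
Z = H the loaded, freely draining top), the deformation gradient is
F = diag(1, 1, λ(Z, t)) and the volume ratio J equals the axial stretch λ.
Quasi-static momentum balance makes the total axial Cauchy stress spatially
uniform at every instant,

    σ_zz(t) = σᵉ_zz(λ) − p,

and mass balance of the incompressible constituents closes the system:

    ∂λ/∂t = ∂/∂Z [ k_eff(λ) ∂p/∂Z ].

Darcy flow uses the van der Voet strain-dependent permeability
k(J) = k₀ Jᴹ.  By default the law is read as a spatial (true) permeability
and pulled back to the material grid, k_eff = k₀ λ^(M−1); setting
`permeability_frame="material"` applies k₀ λᴹ directly.  The two differ
at first order in the strain, and nothing in the source protocols
discriminates between them, so the choice is exposed (at 5–10 % strain the
effect on the reported stresses is well under the variant-to-variant
differences).

### Skeleton energies

Three Neo-Hookean variants are implemented through their confined-compression
axial stress σᵉ(λ) and tangent dσᵉ/dλ (I₁ = 2 + λ², J = λ):

| tag | energy W | σᵉ_zz(λ) | tangent at λ = 1 |
|-----|----------|----------|------------------|
| NH1 | C₁₀(I₁ − 3) − 2C₁₀ ln J | (2C₁₀/λ)(λ² − 1) | 4C₁₀ = 2G |
| NH2 | G/2 (I₁ − 3) − G ln J + (K − 2G/3)/2 (ln J)² | (G/λ)(λ² − 1) + ((K − 2G/3)/λ) ln λ | K + 4G/3 |
| NH3 | C₁₀(Ī₁ − 3) + (1/D₁)(J − 1)² | (4C₁₀/3) λ^(−5/3)(λ² − 1) + (2/D₁)(λ − 1) | 8C₁₀/3 + 2/D₁ = K + 4G/3 |

All three are stress-free at λ = 1 and monotonic on λ ∈ [0.8, 1.2] for the
bundled materials (no instability in the working range).

**The NH1 completion.**  The incompressible-form energy C₁₀(I₁ − 3) alone
carries a nonzero reference stress and cannot constrain J in a consolidating
skeleton, whose volume must change as fluid leaves.  We complete it with the
minimal volumetric term −2C₁₀ ln J, which preserves the stiffness parameter
and deviatoric response and restores a stress-free reference.  This is a
genuine modelling choice: the custom-solver implementation this variant
mirrors is not publicly documented.  Its consequence is quantitative and
worth stating plainly — the completion has aggregate modulus 2G, which at
ν = 0.2 is 25 % below the K + 4G/3 = 8G/3 shared by NH2 and NH3, so NH1's
drained stresses sit ~25–30 % below the compressible variants and the
campaign's all-variant agreement average is dominated by that offset
(measured ≈ 14 % overall versus ≈ 1.1 % for NH2-vs-NH3).  Alternative
completions (e.g. adding a (K/2)(ln J)² term) move NH1 stiffer than NH2/NH3
by a similar margin in the other direction; no simple hyperelastic
completion makes NH1 agree with the compressible forms to a few percent
while remaining distinct from them.

### Material parameters

Each gel is described by (G, ν, k₀, M) with derived C₁₀ = G/2,
K = 2G(1 + ν)/(3(1 − 2ν)), D₁ = 2/K.  The bundled sets (0.20 / 0.30 /
0.40 % collagen by weight, all at ν = 0.2) are stored in
`src/porogel/data/materials.yaml` with explicit unit suffixes; D₁ is kept
in 1/Pa (its table column is conventionally printed in 1/kPa — only that
reading is dimensionally consistent with the (1/D₁)(J − 1)² term).  Loading
the fixtures re-derives every value from (G, ν) and verifies the printed
cells at printed precision (half-up rounding), so a corrupted fixture fails
fast.  Permeabilities are in m⁴/(N·s) ≡ m²/(Pa·s); everything is converted
to SI (Pa, m, s) at the parsing boundary.

### Loading protocols

Two ramp-hold protocols are bundled:

* `busby` — 5 % compression over 10 s, 290 s hold, drainage path 5 mm
  (cylindrical sample geometry).  With the 0.30 % gel,
  τ = H²/(Hₐk₀) ≈ 208 s.
* `chandran` — 10 % compression over 100 s, 2000 s hold, drainage path
  15 mm.  The cuboid sample is 3 × 3 × 15 mm and the source protocol does
  not state which dimension carries the load; we take the 15 mm axis
  because the resulting τ ≈ 1.9 × 10³ s matches the 2000 s relaxation
  window of the experiment, whereas a 3 mm path (τ ≈ 75 s) would be fully
  drained long before the hold ends.  The height is an ordinary protocol
  parameter, so the alternative is one config line away.

## Discretisation

Finite volumes on a fixed uniform material grid: cell-wise constant stretch
λₑ, cell-centred pressure, interface fluxes with arithmetic-mean
conductivities, a half-cell gradient to the p = 0 top surface, zero flux at
the bottom.  The pressure is eliminated through the momentum balance
(pₑ = σᵉ(λₑ) − σ_zz), leaving the N stretches plus the uniform total stress
as unknowns; the total stress acts as the Lagrange multiplier of the
prescribed-displacement constraint Σλₑ ΔZ = H − δ(t).  Time stepping is
fully implicit backward Euler with an analytic-Jacobian Newton solve
(arrowhead system, dense solve; relative residual tolerance 10⁻⁹, simple
step damping to keep λ > 0).  Consequences of this construction:

* total stress is uniform to machine precision by construction;
* the scheme is exactly conservative — the discrete top-face outflow equals
  the mixture-volume loss step by step, so the global mass-balance check
  sits at round-off (≲ 10⁻⁹ relative) rather than at truncation level;
* backward Euler is unconditionally stable for the stiff early-time
  pressure boundary layer at the drained face.

**Time grid.**  Outputs are recorded on 50 uniform ramp steps and hold
steps grown geometrically (factor 1.2) from the ramp step up to
hold/100.  Internally every output interval is subdivided (8 substeps; 32
in the interval immediately after the ramp start and after the ramp/hold
kink).  The reason is the response's √t self-similarity after each
displacement-rate discontinuity: a first-order step into it carries a
pointwise relative error of order 1/k at the k-th step *independent of the
step size*, so refinement must come from extra steps before the first
recorded time, not from a smaller dt.  With these defaults the solver
matches the linear analytic solution to < 0.5 % at every output time
(see verification below); geometric (ratio-2) grading of the first interval
was tried and plateaus at ≈ 3.6 % endpoint error regardless of depth.

**Defaults.**  n_elements = 100, newton_tol = 10⁻⁹, max 30 Newton
iterations.  A campaign run takes on the order of a second; halving both
the time step and the cell size moves the reference peak stress by
≈ 0.02 %.

**Monitored output.**  The reported relaxation curve is the bottom-layer
effective stress reconstructed as p − σᵉ_zz from the bottom pore pressure
and the bottom-layer skeleton stress.  By momentum balance this equals the
compressive total-stress magnitude — the quantity a load cell reports —
which is why it rises during the ramp and relaxes monotonically during the
hold.  Peak values are taken as the maximum over recorded times (no
interpolation); end values are the final sample.

**Sealed faces.**  With drainage disabled on both faces the incompressible
mixture cannot change volume: only a vanishing prescribed settlement is
admissible (the run degenerates to the undeformed state with zero outflow,
pressure gauged to zero), and a finite compression raises a solver error.
A sealed sample under load control would carry the load entirely in the
pore pressure; load control is out of scope.

## Linear verification oracle

With M = 0 and vanishing strain the problem linearises to 1D consolidation
with coefficient c = Hₐk₀, Hₐ = K + 4G/3.  Two classical solutions are
implemented, and they are deliberately distinct:

* **Step load** (Terzaghi): total stress Hₐε₀ applied instantly; pressure
  starts uniform at Hₐε₀ and decays on cos((2n−1)πZ/2H) modes.
* **Displacement control**: the ramp-hold input the solver simulates.  The
  displacement field itself obeys the heat equation with Dirichlet data
  (u(0) = 0, u(H) = −δ(t)), eigenmodes sin(nπZ/H); Duhamel superposition
  over the ramp gives the total stress and bottom pressure.  A true
  displacement *step* has divergent initial stress, which is why the
  step-load idealisation is the one with a finite initial pressure — the
  two families must not be conflated when verifying a
  displacement-controlled solver.

The non-decaying part of the ramp mode sum is summed in closed form
(Σ 2/(μₙt₀) = τ/3t₀, odd modes τ/2t₀), leaving exponentially convergent
series; n_terms defaults to 200 with a truncation-tail warning.  The test
suite cross-checks both families against a brute-force nodal
finite-difference/stiff-ODE solve that shares no code with either, and the
central verification property — nonlinear solver vs displacement-control
series at M = 0, ε = 10⁻³, all three variants — holds to < 1 % at every
output time (measured ≈ 0.4 % max).

## Comparison campaign

`run_campaign` executes {chandran × 0.30 %} ∪ {busby × {0.20, 0.30,
0.40 %}} × {NH1, NH2, NH3} = 12 runs and summarises each by peak and
end-of-hold effective stress.  Percent differences between variant pairs
use the symmetric form 100·|a − b|/((a + b)/2): no variant is privileged,
and for the ≈ 1 % NH2-vs-NH3 differences the symmetric and either-reference
forms agree to first order.  The "average difference" weights peak and end
statistics equally over all cells and pairs; per-pair, per-statistic and
NH1-excluded aggregations are all reported in `differences.json` because
the aggregation behind a single headline number is a genuine free choice.
Measured with the defaults: NH2-vs-NH3 ≈ 1.1 %, NH1 pairs ≈ 20 %
(see the NH1 completion note above), overall ≈ 13.8 %.

Experimental reference curves are not bundled: the characterisation
experiments the protocols come from are published as figures, not tables.
`porogel suite --experimental curve.csv --experimental-cell busby,c030`
compares a user-supplied (time_s, stress_kPa) curve's peak/end values
against one campaign cell.

## What the fixtures do and do not emulate

The bundled materials and protocols are the study conditions themselves
(printed parameter values, printed ramp/hold/strain/geometry), not
synthetic approximations — there is no stochastic data generator in this
problem.  What the 1D model does *not* represent: 3D mesh effects in the
source simulations, platen friction and interface phenomena (explicitly
absent from the modelling the campaign mirrors), osmotic swelling,
viscoelasticity of the solid phase, and fibril-level anisotropy.  Passing
tests therefore demonstrate internal consistency of the constitutive
implementations and of the consolidation solver, and agreement between
constitutive variants — not agreement with laboratory stress curves.

## Known limitations

* NH1's realisation is a completion choice (see above); results involving
  NH1 should be read as properties of that completion.
* The `chandran` protocol's drainage-axis length (15 mm vs 3 mm) is inferred, not
  documented.
* Output quantities are monitored at the first cell centre (ΔZ/2 above the
  bottom face); the distinction from the face value vanishes quadratically
  with grid refinement and is ≪ 0.1 % at the defaults.
* Only confined uniaxial kinematics are exposed; the constitutive layer
  does not provide general 3D stress states.
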