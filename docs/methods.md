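# Methods

`suvphase` models how a ~120 nm lipid vesicle (SUV) whose membrane demixes
into liquid-ordered (Lo) and liquid-disordered (Ld) phases behaves near a
charged target membrane, and implements the annulus-based fluorescence
statistic used to score vesicle fusion in confocal images.  This note
records the model, its numerical treatment, the parameters that matter,
and what the scaled-down study conditions do and do not show.

## Continuum model

The vesicle surface is a fixed sphere Γ of radius R = 60 nm.  The local Lo
area fraction c ∈ [0, 1] (order parameter), tangential mixture velocity
**u**, surface pressure p and chemical potential μ evolve by the surface
Navier–Stokes–Cahn–Hilliard (NSCH) system

    ρ(c) (∂t u + (∇_Γ u) u) − div_Γ(2 η(c) E_s(u)) + ∇_Γ p
        = F_e + F_cap + F_chem − γ u,
    div_Γ u = 0,
    ∂t c + div_Γ(c u) − div_Γ(M ∇_Γ μ) = 0,
    μ = f0′(c) − ϵ² Δ_Γ c,

with the quartic double well f0(c) = ¼ c²(1−c)², degenerate mobility
M = D c(1−c), the Boussinesq–Scriven strain rate E_s(u) = sym(P ∇u P),
convex mixtures ρ(c) = ρ_Lo c + ρ_Ld (1−c) and η(c) likewise, the
capillary force F_cap = λ μ ∇_Γ c (equivalent to the line-tension tensor
form −λ ϵ² div_Γ(∇_Γc ⊗ ∇_Γc) up to a gradient absorbed into p), and the
chemical momentum flux F_chem = M θ² (∇_Γ u) ∇_Γ μ with θ² = dρ/dc
constant.  Temperature does not appear: the model describes the evolution
*after* phase separation has been initiated, whatever initiated it.

Two terms are the package's own modelling decisions:

* **Ambient friction −γu.**  On a free sphere, rigid rotations are Killing
  fields (E_s = 0), so surface viscosity cannot damp the collective
  rotation that reorients the charged patch; an undamped model rings like
  a pendulum instead of creeping monotonically the way phase-separated
  vesicles are observed to reorient.  The friction term models momentum
  exchange with the surrounding water, with coefficient
  `bulk_friction` = 2·10⁶ Pa·s/m (order of water viscosity over a
  sub-nanometre slip length; membrane–water friction coefficients quoted
  in the literature span 10⁶–10⁹ Pa·s/m).  It acts identically on every
  formulation, so cross-composition time *ratios* are unaffected by its
  exact value in the overdamped regime.
* **Electrostatic coupling scale.**  See "Electrostatics" below.

### Line-tension calibration

The free energy is E[c] = λ ∫_Γ [f0(c) + (ϵ²/2)|∇_Γ c|²] ds.  A planar
interface of the quartic well has line tension λ ϵ ∫₀¹ √(2 f0) dc =
λ ϵ √2⁄12, so λ = (12/√2) σ_γ / ϵ ties the model to the physical line
tension σ_γ (1.2–1.8 pN, range midpoints per formulation) *at the
interface width actually simulated*.  When ϵ is widened for a coarse mesh
(below), λ is recalibrated so the physical line tension is preserved.

### Electrostatics

The micron-scale target vesicle (GUV) is approximated as an infinite
plane below the sphere.  Measured zeta potentials are converted by the
low-potential (linearized Grahame) relations Ψ0 = ζ e^{−κx},
σ = ε_r ε0 κ Ψ0 with κ = 10/7 nm⁻¹ and slip plane x = 0.24 nm; the plane
field is E = σ_GUV/(2ε0) (uniform, so the stand-off distance is
irrelevant) and the vesicle's total charge is Q = σ_SUV · 4πR².  The GUV
zeta potential was measured in sucrose and the SUV ones in dilute PBS;
both are used as measured, without a medium correction.

The charge splits between the phases according to the DOTAP partition:
with per-phase DOTAP concentrations c_Ld, c_Lo and Lo area fraction a_D,
the Ld phase carries f_Ld = c_Ld(1−a_D) / [c_Ld(1−a_D) + c_Lo a_D] of the
total charge (67.15% for PAT3).  On the diffuse-interface field the phase
indicators are the smooth weights w_Ld = 1−c, w_Lo = c; each share is
spread uniformly over its phase, the per-area force is the local charge
density times |E| directed toward the plane, and the normal component is
projected out (a rigid sphere held at fixed distance cannot move
normally; only the tangential component drives reorientation).  The
area-weighted charge density integrates to Q exactly by construction.

Taken at face value, the tabulated constants put the electrostatic force
three orders of magnitude above the capillary force, a regime in which
the patch would be shredded rather than slide intact, and the nominal
D = 10⁻⁵ cm²/s makes the diffusive time unit R²/D ≈ 3.6 µs, irreconcilable
with minute-scale coarsening; the original calibration chain is described
as data-driven and is not recoverable.  The package therefore works in
model units (lengths in R, time in R²/D), treats cross-composition
*ratios of times* as the primary observables, and scales the
electrostatic force by one global dimensionless coupling
(`electro_coupling` = 3.5·10⁻³, chosen once so the forced dynamics stay
in the creeping, compact-patch regime).  The coupling multiplies every
formulation's force equally, so it cancels from ratios.

## Discretization

* **Mesh.**  Icosahedral-subdivision sphere (10·4^L + 2 vertices at level
  L), vertices snapped to the sphere.  P1 (piecewise-linear) fields;
  lumped (barycentric) vertex areas for all integrals, which makes the
  discrete Cahn–Hilliard mass balance telescope exactly: ∫c ds is
  conserved to direct-solver round-off (~10⁻¹⁵ relative in practice).
* **Operators.**  Exact per-face P1 gradients; divergence defined as the
  negative adjoint of the gradient in the area-weighted inner products
  (so the discrete Stokes identity holds to round-off); the induced
  Galerkin Laplace–Beltrami (cotangent) operator reproduces spherical
  harmonic eigenpairs within 1.6% (l ≤ 4, level-4 mesh) and converges
  with refinement; the strain rate sym(P∇uP) vanishes to machine
  precision on rigid rotations.
* **Time stepping.**  Operator splitting per step: a Cahn–Hilliard step,
  then a momentum step.  The CH step is backward Euler with Newton on
  f0′ (the per-step energy minimizer of the gradient flow; strictly
  dissipative for any dt), mobility and advection lagged at the old
  state; a linearly-stabilized IMEX variant (one solve, energy stable
  for S ≥ max|f0″|/2) is available as `ch_scheme="stabilized"`.  The
  momentum step is implicit in viscosity, friction, inertia and
  pressure, explicit in convection and forces, solved in per-vertex
  orthonormal tangent bases so the velocity is pointwise tangential by
  construction; incompressibility is enforced weakly by stabilized
  P1–P1 (Brezzi–Pitkäranta, δ = 0.2 h²/2η_Ld, plus a 10⁻⁹ mass
  regularization fixing the constant pressure mode).
* **Mobility extension.**  The continuum model keeps c in [0, 1]; the
  discrete solution overshoots by a few percent at thin interfaces.  The
  time stepper extends the degenerate mobility outside [0, 1] by
  reflection, |c||1−c|, rather than clipping to zero: clipping strands
  the overshoot exactly where the mobility vanishes and the excess then
  grows without bound, while the reflected extension lets it relax and
  keeps overshoot at the percent level.  The exported `mobility` function
  is the clipped form.
* **Adaptive time step.**  dt ∈ [4·10⁻⁶, 4] model units, grown by 1.3 while the per-step c-increment
  and CFL number are small, halved on rejection (increment > 0.05,
  CFL > 0.5, overshoot beyond tolerance, or solver failure), with a
  feed-forward CFL cap from the current velocity and a short growth
  cooldown after rejections.

## Interface width and the scaled-down study conditions

The physical interface width is ϵ = 1 nm = R/60, resolvable only on
meshes far beyond one-CPU scale, so simulations floor ϵ at 1.2 mean mesh
edges by default.  This has a thermodynamic consequence: widening ϵ
raises the interface energy λϵ√2/12·L relative to the bulk term, and for
the PAT1 formulation (a_D = 0.108, *outside* the spinodal band
0.211 < c < 0.789 of the quartic well) the fully separated state stops
being the free-energy minimum at all for ϵ̂ ≳ 0.064.  In the same regime
the critical nucleus (≈ 3.6 ϵ̂ in radius) outsizes the clusters present
in vertexwise Bernoulli noise, so a strictly dissipative integrator
correctly relaxes PAT1 to the metastable uniform state — off-spinodal
nucleation from deterministic dynamics is resolution-limited.

The comparative study (coarsening and reorientation times across
formulations) therefore runs at fixed, documented conditions chosen once:

* level-3 mesh (642 vertices), ϵ̂ = 0.06 (below PAT1's two-phase
  threshold, marginally under-resolved at h ≈ 0.13), λ recalibrated to
  the physical line tension at that width;
* initial mixture drawn on a coarse icosahedral lattice
  (`noise_level=1`, 42 cells; exactly round(a_D·42) cells pure Lo at
  random positions, mapped to the mesh by nearest cell centre).  This
  preserves the *amplitude* of composition fluctuations at a fixed
  physical scale as the mesh is coarsened — the role that fine-mesh
  vertexwise noise plays at reference resolution — and guarantees
  supercritical nuclei for the off-spinodal formulation.  Vertexwise
  i.i.d. Bernoulli initialization (`initial_state`) remains the default
  and is what the conservation runs use;
* overshoot allowance 0.15 in the step controller (the under-resolved
  forced runs develop a persistent structural overshoot near 0.05–0.07;
  at default, resolved conditions overshoot stays below 0.05);
* backward-Euler CH scheme, five replicate seeds (master+0..4), and the
  worst-case stage-B start (field rotated so the Ld centroid sits at the
  pole opposite the membrane, fluid restarted at rest).

Observed at these conditions (five seeds): mean time to the single-patch
equilibrium ≈ 11 (PAT1), ≈ 1100 (PAT2), ≈ 260 (PAT3) model units; mean
reorientation time ≈ 163 (PAT1) > 72 (PAT2) > 48 (PAT3).  Two known
relations for this system are reproduced: the large-domain formulation needs more than
double the coarsening time of the small-domain one (ratio ≈ 20), and
reorientation is fastest for the formulation with the densest charged
patch, in the right order across all three.  Two are not: (i) the
equilibrium-time *ordering* places PAT2 above PAT3 here — PAT2's minority
fraction (0.346) exceeds PAT3's (0.296) and its near-bicontinuous
morphology coarsens slowest, whereas at full resolution the ordering
tracks a_D through viscosity-dependent hydrodynamic coalescence, which
this scale does not reproduce; (ii) the PAT1/PAT3 reorientation ratio is ≈ 3.4
rather than ≈ 10.  The second gap has a closed-form explanation: the net
torque on a cap configuration is E·Q·|x̄_q| sinφ with x̄_q the charge
centroid.  For PAT1, 96% of the charge sits on 89% of the surface, so the
two phases' centroid contributions nearly cancel (|x̄_q| ≈ 0.069 R
against 0.375 R for PAT3), bounding the overdamped time ratio near
(Q₃|x̄_q₃|)/(Q₁|x̄_q₁|) ≈ 6 before detection effects; the measured 3.4 is
consistent with that bound and insensitive to the friction and coupling
scales, which cancel from the ratio.

### Equilibrium and reorientation detection

The equilibrium state is "one patch of the minority phase".  A
single-patch state is *confirmed* when the minority component count
(triangle-edge connectivity, threshold 0.5) equals 1 at every accepted
step of a 10-step trailing window whose relative free-energy change is
below 10⁻⁴ (both configurable); the *reported* equilibrium time is when
that confirmed count run began, i.e. when the final patch formed.  The
window end is not used as the time stamp: at scaled conditions it is
dominated by a composition-independent slow relaxation tail (hundreds of
model units of asymptotic energy flattening at the dt ceiling), which
measures the step controller rather than coarsening.  Reorientation time
is the first stage-B time the Ld centroid angle to the facing pole drops
below π/6 and stays below it for the trailing window; "facing the
membrane" has no standard quantitative definition and π/6 is this
package's documented choice.
Runs that never meet a criterion return NaN and are excluded from
replicate averages, with counts reported.

## The synthetic confocal generator

`synth_confocal` renders anti-aliased bright rings (4×4 subpixel
coverage) for each vesicle on a constant background in two channels — a
marker channel in which every GUV is bright and a fusion-signal channel
at each vesicle's membrane intensity — plus additive Gaussian noise,
deterministic under a seed, with a ground-truth table and overlap flags.
It emulates well-separated, in-focus equatorial sections with known rim
brightness.  It does not emulate out-of-focus light, shading, detector
nonlinearity, vesicle clutter or segmentation ambiguity, so passing
round-trip tests validate the *measurement arithmetic* (annulus means,
background subtraction, strict IM > 1 calls, ≥ 5 µm filter), not
robustness to real microscopy artefacts.  Measurement annuli for
synthetic fields are drawn inside the flat core of the rendered rim, so
the zero-noise round trip is exact by construction; region placement on
real images remains the user's responsibility, as in the laboratory assay.

## Parameters (defaults)

| parameter | value | units | meaning |
|---|---|---|---|
| R (`suv_radius`) | 60 | nm | vesicle radius (120 nm diameter) |
| a_D | 0.108 / 0.3457 / 0.7037 | – | Lo area fraction (PAT1/2/3) |
| ρ_Lo, ρ_Ld | 1401–1435, 1172 | kg/(mol·Å²) | molar area densities, converted via N_A |
| η_Lo, η_Ld | 3.1–6.5, 0.3 | 10⁻⁸ Pa·s·m | surface viscosities (range midpoints) |
| σ_γ | 1.3–1.5 | pN | line tension (range midpoints) |
| ϵ (`eps_interface`) | 1 | nm | interface width (floored at 1.2 h on coarse meshes) |
| D | 10⁻⁵ | cm²/s | mobility scale; sets the model time unit R²/D |
| κ, x, ε_r, ε0 | 10/7, 0.24, 80, 8.85·10⁻¹² | nm⁻¹, nm, –, F/m | electrolyte constants |
| ζ | −8.56; 18.35/18.87/20.41 | mV | zeta potentials (GUV; PAT1/2/3 SUVs) |
| `bulk_friction` | 2·10⁶ | Pa·s/m | ambient drag (overdamps rigid rotation) |
| `electro_coupling` | 3.5·10⁻³ | – | global electrostatic force scale (ratio-preserving) |
| IM threshold | 1.0 | raw units | strict fusion call on raw intensities |
| diameter filter | 5 | µm | minimum GUV size in the denominator |

## Known limitations

* Absolute times are in model units; an absolute experimental calibration
  is not recoverable, so only time ratios are compared.
* The sphere is rigid and fixed: no shape change, bending elasticity,
  thermal noise, multi-vesicle interaction, or actual fusion mechanics.
* Off-spinodal nucleation depends on the initial-noise scale; the
  coarse-lattice mixture is a scaled-down surrogate, not molecular
  reality.
* The P1–P1 momentum solve enforces inextensibility weakly; the
  pointwise divergence residual is percent-level relative to the
  velocity gradient, and a surface-gradient force is absorbed by the
  pressure up to stabilization leakage (~an order below the driven flow).
* Phase partitions (per-phase lipid fractions) are input data taken
  verbatim from rounded tables, not computed from tie lines.
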