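# Methods

## Problem and model

An RF coil drives time-harmonic fields (e^{+iωt}) in a voxelized dielectric
body. Introducing a small, highly conductive object (a medical implant)
changes the electric field, and with it the local specific absorption rate
(SAR), only through the object's added material contrast. On a Yee grid the
frequency-domain Maxwell system is

    (D + C) f = -q,

with D the discrete curls, C = diag(σ_e + iω ε_e) the edge-averaged
admittivity, and q the source current density on the coil edges. Writing the
implant as an additive contrast C̃ = diag(σΔ + iωΔε) on its M edges (selector
S), the Sherman–Morrison–Woodbury identity turns the re-solve into a rank-M
update of the background field f^bg:

    f = f^bg + Z (I - C̃ SᵀZ)⁻¹ C̃ Sᵀ f^bg,     Z = -(D + C^bg)⁻¹ S.

The N×M library matrix Z is never materialized. The outer Krylov solve
(GMRES) needs only products Zx — the field radiated by a trial scattered
current density x on the implant edges — and these are produced on the fly by
a volume-integral-equation (VIE) solve on a subdomain around the implant:

    E^t = E^inc(x) + (I + ∇∇·/k_b²) ∫ G χ_bg E^t dV,

with G the scalar free-space kernel, χ_bg = -iωμ0(σ_e + iωΔε_e) the
background contrast, and the integrals evaluated as FFT convolutions.
The magnetic field update is H = H^bg + ∇× ∫ G S diag(x) Sᵀ dV, with the curl
taken by the Yee face stencil. (The unknown x has units A/m²; dimensional
analysis fixes the H update without an extra iω factor.)

A brute-force full-domain solver (sparse direct factorization of the E-only
curl-curl reduction, perfect-electric-conductor outer box) provides the
reference: background fields, with-implant oracle solutions, and — on tiny
problems — the explicit Z for algebra-level checks.

## Kernel discretization: lattice-consistent Green's function

The decisive numerical choice in this package is the Green's kernel. The
reduced M×M system (I - C̃SᵀZ) is ill-conditioned for metallic implants
(‖x‖ ≫ ‖b‖: the currents enforce near-zero total field inside the metal), so
the update inherits kernel-level disagreement between the VIE and the
background solver amplified many-fold. Measured on the standard phantom:
point-sampling the continuum kernel e^{-ikr}/4πr gives reduced matrices that
differ from the Yee reference by ~10%, which the solve amplifies to ~70%
field-update error. The kernel therefore reproduces the *discrete* operator:

* scalar samples are the lattice Green's function of the 7-point Laplacian,
  g(o) = ∫₀^∞ e^{-6t} I_ox(2t) I_oy(2t) I_oz(2t) dt, evaluated via a
  Gaussian-surrogate split of the Bessel-product integral (g(0) = 0.25273…,
  Watson's integral; g(0) - g(neighbor) = 1/6 exactly). Samples are dressed
  with the continuum retardation phase e^{-ik_b r_eff}, r_eff = h/(4π g(o)),
  exact in the static limit and accurate to O((k_b r)³) corrections — at
  5 mm / 64 MHz, k_b r < 0.2 everywhere in a subdomain;
* the ∇∇·/k_b² correction uses the same staggered central differences as the
  reference solver (edge → node divergence, node → edge gradient). Because
  ∇×∇× = ∇∇· - ∇² holds exactly for these stencils, the composite dyadic
  kernel equals the infinite-lattice inverse of the vacuum curl-curl
  operator up to the retardation dressing.

With this kernel the reduced matrices agree with the explicit reference
library to ~0.1% and the solved currents to ~0.2%. The deliberate trade-off:
the incident field of a single edge reproduces the *discrete* dipole, whose
worst-case on-axis deviation from the closed-form Hertzian dipole at three
voxels is ~35-40% (a lattice property the reference solver shares; the
median deviation is ~3% and decays as h²/r²). A kernel that matched the
closed form pointwise at three voxels was implemented and rejected: it
cannot simultaneously match the discrete background solver, and
oracle-equivalence of the full update is the property the method exists for.

The 3×3 circulant kernels are embedded with three extra offset shells
(`pad`) so staggered differences across the subdomain boundary act on true
convolution values; differencing into implicit zeros is amplified by
1/(h²k_b²) ~ 4·10⁴ at this scale and produced order-unity boundary artifacts
before this fix.

## Solver structure, tolerances

* Outer: full (unrestarted) GMRES on the admittivity-normalized form
  (C̃⁻¹ - SᵀZ)x = Sᵀf^bg, right-preconditioned by the diagonal estimate
  C̃⁻¹ - z_self. The textbook form I - C̃SᵀZ has norm ~|C̃ z| ≈ 10³-10⁴ for
  titanium and amplifies the inexactness of the matrix-free products until
  GMRES stalls; the normalized form keeps every entry on the library-matrix
  scale. Both forms share the exact solution, and the reported residual is
  ‖b - g(x)‖/‖b‖ of the original system, evaluated through the stable form.
  Stopping: -50 dB (relative residual 10^(-50/20) ≈ 3.2·10⁻³), the
  convention also applied to the reference solves.
* Inner (VIE): CGS, default -100 dB. The outer recurrence needs matrix-free
  products accurate to roughly κ(VIE)⁻¹ of its own target; for tissue-grade
  contrast (εr ≈ 50) κ ≈ 50, and -50 dB inner products stall the outer
  solve, while inner solves cost ~1 s at desk scale, so the tight default
  is cheap. Both tolerances are independent configuration fields.
* Zero right-hand side short-circuits bit-exactly (x = 0, f = f^bg, H = H^bg).
* FFT sizes are `next_fast_len(2(n+pad)-1)` per axis (exact aperiodic
  convolution).

## Standard validation phantom

24³ voxels, 5 mm isotropic, 64 MHz (1.5 T): a two-voxel-thick tissue slab
(σ = 0.5 S/m, εr = 50, ρm = 1000 kg/m³) inset three voxels from the domain
box; a 10-voxel (50 mm) titanium rod (σ = 2.4·10⁶ S/m) in the top slab
layer; a square 1 A current loop (half-side 5 voxels, normal z) nine voxels
above the tissue, satisfying the small-perturbation premise (implant fields
are negligible at the source, which is held fixed). The rod lies directly
beneath one loop leg, parallel to the strongest tangential electric field —
the elongated-conductor configuration whose tip enhancement the method must
capture. Problem sizes throughout (24³ reference, ≤16³ identity checks,
15³ dipole boxes) are desk-scale choices that keep the full validation suite
in minutes on one CPU while leaving every mechanism of the method active.

### Comparison protocol

The perturbation pipeline (reference background + matrix-free update) is
compared voxelwise in interpolated |E| and in local/1 g SAR against the
brute-force solve with the implant. Two protocol parameters follow from the
desk-scale reference, not from the method:

* FFT margin: the validation run uses margin 12, the value at which the
  margin sweep {2, 4, 8, 12} plateaus — the same grow-until-no-improvement
  rule the method prescribes in production; on this phantom it covers every
  tissue voxel.
* Wall buffer: the reference's conducting box perturbs the solution near the
  walls, where an open-space update cannot (and should not) follow it.
  Re-solving an identical phantom in a box enlarged by two vacuum voxels per
  side moves the |E| magnitude by a median 34%, 28%, 16%, 7.7% and 4.0% at
  wall distances 0-4: the box's own footprint crosses the 5% comparison
  level between three and four voxels from the wall. Comparisons therefore
  exclude voxels closer than four voxels to the box (`WALL_BUFFER = 4`).
  Tissue never approaches the box closer than three voxels by construction.

## SAR post-processing

Edge fields are interpolated to voxel centers (mean of the parallel edge
pairs), and local SAR = σ|E|²/(2ρm) under the peak-amplitude phasor
convention (the ½ would be absent for RMS phasors; the convention only
rescales all maps). Mass averaging grows a centered cube in whole voxels
until it holds the target tissue mass (1 g default; vacuum contributes no
mass; cubes clip at the domain box) and takes the mass-weighted mean — a
reproducible simplification of regulatory cube averaging without the IEC
62704 face-validity rules. Because both SAR maps share one mass map, the
averaging operator is identical for both methods and can only shrink their
difference (the contraction the tests assert). Desk-scale SAR values are
meaningful as ratios and differences; no absolute W/kg claims are made
(coil drive normalization is arbitrary).

## What the synthetic phantoms do and do not show

The generator produces uniform slabs, spheres and cylinders with piecewise
constant tissue, ideal loop/dipole current sources, and parametric implants
(rod, plate, hollow cage). This exercises every mechanism of the method —
high-contrast tissue, metallic implants, tip field enhancement, margin
truncation — but not anatomical heterogeneity, realistic coil drive, or
implant geometries with sub-voxel features. Passing the suite shows the
update reproduces the brute-force discrete solution under the stated
conditions; it does not by itself validate absolute SAR in tissue-realistic
anatomy, which requires anatomical models outside this package's scope.

## Known limitations

* The reference uses a PEC box; fields within a few voxels of it are
  boundary artifacts of the desk-scale oracle, not of the update method.
* The update region is the FFT subdomain; the field change outside it is
  taken as zero. Dispersed multi-implant updates need either a larger
  subdomain or sequential application (which ignores implant-implant
  coupling).
* Non-magnetic, isotropic, non-dispersive materials only; uniform isotropic
  resolution; the coil current is assumed unperturbed by the implant.
* The incident operator matches the discrete, not the continuum, near field
  (see the kernel section); at ≥5 voxels the two agree to a few percent.
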