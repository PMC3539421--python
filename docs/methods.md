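# Methods

## Model

The lung lobe is a saturated poroelastic continuum: air is the pore fluid,
parenchyma the skeleton.  Two fields are solved on one tetrahedral mesh.

**Pore pressure.**  A Richards-type balance of storage, Darcy flux and
skeleton dilatation,

    φβ ∂p/∂t = ∇·[ k/μ (∇p + ρ_air g) ] − ∂(∇·u)/∂t ,

with porosity φ, air compressibility β, permeability k, air viscosity μ.
The dilatation-rate term is the two-way coupling: expanding tissue draws
pressure down, and pressurized pores push tissue outward.

**Displacement.**  The quasi-static poroelastic Navier equation,

    G ∇²u + G/(1−2ν) ∇(∇·u) = ∇p − f ,

with shear modulus G = YM/[2(1+ν)] and Poisson ratio ν.  Orthotropic
anisotropy enters exactly as three plane-wise shear moduli (G_xy, G_yz,
G_xz); the volumetric 1/(1−2ν) term uses the element-mean G and a single ν.
Inertia is neglected (breathing time scales are far above the elastic wave
time of this soft, light tissue).

**Pressure–structure coupling form.**  The ∇p load is assembled in its
integrated-by-parts (Biot) form, ∫p(∇·v)dV: equivalently a −∇p body load
plus pore pressure acting as traction on the otherwise traction-free
surface, i.e. the exterior is free of *total* stress.  This choice is
essential, not cosmetic: with a volume-only −∇p load a spatially uniform
pore pressure would produce zero deformation, so the lobe could not inflate
in phase with the drive and every displacement peak would track the
*rate* of pressure change (quarter-period early) instead of the pressure
itself.  The by-parts form makes a uniform pressure p produce the exact
homogeneous dilation u = αx with α = p/(G + 3λ), λ = G/(1−2ν) — a linear
field that P1 elements reproduce to machine precision, which the test suite
uses as a closed-form oracle.

## Phantom geometry

The synthetic lobe is an ellipsoid (default semi-axes 6 × 8 × 12 cm, human
lobe scale) partitioned into concentric scaled-ellipsoidal shells — a
surrogate for the branching airway tree in which zone 1 (core) holds the
wide conductive branches and outer zones progressively narrower ones.
Meshing places seed points on concentric layers (golden-angle spirals with
seeded jitter and random layer rotations), graded so the per-shell target
edge length refines toward the core, and tetrahedralizes them with Delaunay;
since the ellipsoid is convex this yields a watertight fill whose surface is
the hull of the outermost layer.  All tetrahedra are re-oriented to positive
signed volume; degenerate elements abort generation.  Generation is
bit-reproducible for a fixed (spec, seed).

Boundary patches: the **inlet** is the set of surface nodes within
`inlet_radius` (default 2.5 cm) of the superior pole — the trachea side;
the **fixed** patch is the surrounding annulus out to `fixed_radius`
(default 4.5 cm), disjoint from the inlet, anchoring the hilum and removing
rigid-body modes; the rest of the surface is free.  Boundary conditions:
pressure Dirichlet (the drive) on the inlet, zero flux elsewhere; zero
displacement on the fixed annulus, total-stress-free elsewhere.

Delaunay meshes of jittered point layers contain some boundary slivers
(near-degenerate, large circumspheres).  They are harmless to the direct
sparse solver used here; mesh-size checks in the tests therefore use the
bulk (99th-percentile) circumradius rather than the sliver-dominated
maximum.

## Material fields

**Permeability.**  Zone-wise branch radii R_z give k = φR²/8 per element.
Defaults: radii (4, 1.5, 0.5) mm from core to periphery — main-bronchus to
small-airway scale — with φ = 0.5, hence k = (1.0, 0.14, 0.016)·10⁻⁶ m².
A dimensionless permeability scale (range of interest 0.01–0.1, default
0.05) uniformly rescales the profile for sensitivity studies; the
deformation is insensitive over that range because pressure filling stays
quasi-static throughout it.

**Airway supply channel.**  A cylinder (default radius 2 cm) from the inlet
patch to the mesh centroid carries core permeability.  Without it the inlet
would feed the whole lobe through peripheral small-airway tissue, and the
diffusive access resistance of that bottleneck (~0.07 s for the defaults)
would make even a homogeneous lobe lag the drive — the phantom would model
air seeping through pleura rather than flowing down a bronchus.  The channel
restores the physiological topology: drive → conductive core → periphery.

**Elasticity.**  Three modes:

* `isotropic` — uniform YM (default 178 Pa), the linear reference case.
* `anisotropic_synthetic` — a stand-in for an image-derived stiffness map.
  Seeded white noise per element is smoothed by iterated face-neighbour
  averaging (pass count ∝ (ℓ/h)², giving correlation length ℓ, default
  5 cm — organ-scale coherent soft/stiff regions).  Because averaging
  concentrates the marginal distribution near its centre (which would make
  the field effectively homogeneous with only isolated extremes), the
  smoothed field is rank-uniformized, then mapped through the monotone
  power law YM = YM_min + (YM_max−YM_min)·u^γ with γ solved by bisection so
  the element-volume-weighted mean is exactly the prescribed value.  This
  attains the range endpoints exactly (no clipping) and matches the mean to
  solver precision.  Defaults: 10–500 Pa, mean 178 Pa.  An optional
  spherical tumor inclusion is pinned at YM_max (rigid).  Plane-wise moduli
  are the scalar field times the axis-contrast triple, default
  (1.2, 1.0, 0.8) — moderate orthotropy whose arithmetic mean is exactly 1,
  so the plane-averaged modulus preserves the scalar-field statistics.
* `anisotropic_file` — per-element YM (or three plane-wise YMs) from a CSV
  table, for patient-derived maps.

**Fluid and tissue constants.**  ν = 0.4, tissue density 700 kg/m³;
air at ambient conditions: ρ = 1.2 kg/m³, μ = 1.8·10⁻⁵ Pa·s,
β = 1/101325 Pa⁻¹ (isothermal ideal gas).  All configurable.

**Drive amplitude.**  Default 20 Pa (sin², period 4 s).  With tissue of
~178 Pa stiffness this produces millimetre-scale displacements on the
decimetre organ, consistent with the model's small-strain, fixed-mesh
(total-Lagrangian) kinematics; a hundreds-of-pascals drive would imply
order-one strains that the linear kinematics could not represent.  Because
the whole system is linear, amplitude only scales the response.

## Discretization and coupling

Galerkin P1 tetrahedra for both fields on the same mesh; lumped storage;
backward Euler in time (default dt = 0.02 s, 200 steps per 4 s cycle —
unconditionally stable for the stiff coupled system).  The discrete
dilatation coupling is one sparse matrix Q: −Q·(du/dt) is the flow source
and Qᵀp the elastic load, the usual symmetric Biot structure.

Each step runs a staggered fixed-point loop — flow solve with the latest
displacement rate, then elastic solve with the new pressure, under-relaxed
(default 0.7) until the combined relative update falls below 10⁻⁶ (max 50
iterations; non-convergence logs a warning, the step is still accepted).
The flow solve is **fixed-stress stabilized**: the storage diagonal is
augmented by the inverse drained bulk modulus (1/K_dr, K_dr = λ + 2G/3 per
element) and the same term applied to the previous iterate is added to the
right-hand side, so the augmentation cancels identically at convergence.
This is required here: air's compressibility contributes only
φβ ≈ 5·10⁻⁶ Pa⁻¹ of storage while the skeleton compliance is
~1/K_dr ≈ 3·10⁻³ Pa⁻¹, a regime in which the plain drained split diverges.
Typical converged iteration counts are 8–15 per step.

Both system matrices are constant in time (linear kinematics, fixed mesh)
and are LU-factorized once per run; a coupling iteration costs two
triangular solves.  A zero-amplitude drive yields exact zeros at every step,
and doubling the amplitude doubles the response to solver tolerance.

## Kinematic measures

* **Hysteresis lag**: within-cycle peak time of a landmark component's
  |displacement| (discrete argmax refined by a local quadratic fit; ties
  resolved toward the earliest sample), minus the drive's mid-cycle peak
  time, wrapped into ±period/2.  Flat traces report no lag.  A circular
  cross-correlation estimate is provided as a robustness cross-check;
  the peak lag is primary.
* **Cycle stability**: smallest cycle whose peak all later cycles match
  within a relative tolerance (default 5%).
* **Loop gap**: consecutive-cycle 3D trajectories resampled at matched
  phases; maximum pointwise distance per pair.
* **Super-cycle period**: autocorrelation of the per-cycle peak sequence
  (lags ≥ 2 cycles, significance threshold 0.3); needs ≥ 8 cycles.
* **TDE**: mean/max Euclidean distance (mm) between predicted and reference
  landmark displacement vectors per breathing phase.

Default landmarks: the surface node farthest from the inlet (distal pole,
"A"), and the most lateral/medial surface nodes near mid-height ("B", "C"),
excluding inlet/fixed nodes.

In comparison reports, the linear-case phase check is evaluated on
components carrying at least 10% of a landmark's dominant component peak:
below that amplitude the peak-time estimator reads mode-mixing residuals of
the multizone permeability structure (a dt-independent ~0.02 s offset on a
~2%-amplitude component in the reference run) rather than the drive
response.  The anisotropic hysteresis witness intentionally considers every
component, since hysteresis genuinely appears first on the lateral
components of the polar-anchored phantom, whose dominant motion is the
in-phase inflation direction.

## What the synthetic conditions do and do not show

The generator reproduces the study's *statistics* (YM range and mean,
permeability law, drive period) on an ellipsoidal phantom, not a patient
anatomy.  Passing tests therefore demonstrate the mechanism — heterogeneous
anisotropic elasticity converts an in-phase poroelastic response into
spatially varying hysteresis — but patient-specific magnitudes (particular
lag values per node, peak-displacement ratios, target deformation errors
against 4DCT) depend on the real geometry and elasticity map and are not
reproduced here.  Hysteresis strength varies with the field realization:
across seeds, the maximum landmark lag of the default anisotropic case
ranges from about one to eight time steps; the packaged demo uses seed 0.

A further structural limitation: the model is linear and time-invariant, so
after its transient the response is exactly cycle-periodic.  Multi-cycle
peak modulation (super-cycle periodicity) can be *measured* by the analysis
module but is not *generated* by this solver; in the simulations it appears
only as a decaying transient signature.

## Numerical edge cases

Degenerate inputs are rejected with specific errors: non-increasing shell
fractions or branch radii, ν ≥ 0.5 (singular volumetric term), empty fixed
patch (rigid-body null space), dt > period/20 (waveform under-resolution),
inverted tetrahedra (named element index), non-tetrahedral cells, and
non-watertight meshes (named face).  Meshes too coarse to populate every
shell abort with a sizing hint.  Problem sizes in the tests are kept small
(phantoms of roughly 400–6000 tetrahedra, consolidation columns of 48–96
elements), which resolves every verified behaviour while keeping the whole
suite under a minute.
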