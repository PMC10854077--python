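# Methods

## Problem and scope

`marrowflow` computes the fluid shear stress (FSS) that loading-induced
marrow flow exerts on the trabecular surface of a cube-shaped cancellous
bone sample, and the downstream statistics used to compare experimental
groups (healthy control, type-2 diabetes, and four verapamil dose arms).
The pipeline is voxel-native end to end: geometry, elasticity, flow and
postprocessing all live on the same 18 µm lattice, replacing
surface-mesh workflows (smoothing, tetrahedral meshing) entirely.

## Synthetic geometry

Real study geometries come from micro-CT scans that are not deposited; the
generator stands in for them. A Gaussian random field — white noise smoothed
by an isotropic Gaussian kernel — is thresholded to the target solid
fraction, then cleaned so that the solid is one face-connected component and
every pore voxel is face-connected to the outer fluid margin (sealed
cavities become solid; stray fragments become pore). Both properties are
required for the discrete operators to be non-singular.

Parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `pitch` | 18 µm | voxel edge; matches the scan resolution the study states |
| `grid_n` | 48 | voxels per core edge (0.864 mm, near the study's 0.8 mm cube) |
| `margin_vox` | 2 | fluid shell around the core (study margin 0.03 mm ≈ 1.7 voxels) |
| `correlation_length` | 120 µm | kernel scale; gives strut widths of 60–120 µm |
| `bvtv_target` | group value | solid fraction; the six groups are 76.8, 23.7, 12.96, 28.85, 32.16, 49.06 % |

Near the percolation threshold of Gaussian level sets (solid fractions
≈ 0.13–0.25 at this correlation length) the cleanup step removes a large
disconnected fraction, so a one-shot quantile threshold can miss the target
BV/TV by up to ten percentage points. Because group identity *is* the bone
volume fraction, the threshold is corrected by bisection on the pre-cleanup
fraction (the post-cleanup fraction is monotone in it) plus a greedy
voxel-level refinement that adds the highest-field pore voxels adjacent to
the cluster or removes the lowest-field surface voxels. Measured accuracy:
|BV/TV − target| ≤ 0.011 over ten seeds at each of the six group levels
(48³ cores). Some low-BV/TV seeds produce a percolating cluster that does
not touch both loading faces; these are reported as errors by the solid
solver and batch runs simply take the first n feasible seeds.

**What the generator does not emulate.** Real trabecular bone is anisotropic
(struts align with principal loading), plate-and-rod structured, and its
architecture co-varies with disease state (diabetic bone has thinner, more
rod-like struts, not just fewer of them). The isotropic, single-scale GRF
reproduces BV/TV, strut scale and topology class, nothing more. Consequences
are discussed under “Known limitations”.

## Loading

Three boundary data, all `T`-periodic with period 1 s:

* top-face displacement `u(t) = B/2 [sin(2π(t − T/4)/T) + 1]`, B = 0.8 µm;
* lateral spring traction `−k (U_solid − U_0)`, k = 16×10⁹ N/mm² per mm of
  displacement (1.6×10¹⁹ Pa/m), U₀ = 0;
* outer fluid pressure `P(t) = C/2 [sin(2π(t − T/4)/T) + 1]`, C = 667 Pa,
  applied identically on all six faces.

The printed unit of k is a pressure; it is interpreted as a stiffness per
unit area (traction = k × displacement in mm) and kept configurable with an
explicit unit string. At this magnitude the lateral faces are effectively
pinned; the solvers tolerate the resulting stiff Robin term through Jacobi
scaling. The spring acts on the face-normal displacement component by
default (`spring_components="all"` pins all three): a normal-only foundation
is the natural model of surrounding-bone support and is the only variant
consistent with a uniform uniaxial-strain state on a homogeneous block,
which the patch test verifies against the constrained-modulus closed form
E(1−ν)/((1+ν)(1−2ν)).

## Solid solver

Standard voxel micro-FE: every solid voxel is a trilinear hexahedral element
with full 2×2×2 Gauss integration; E per group (11.28–15.08 GPa), ν = 0.3.
Quasi-static: at 1 Hz and ~0.1 % strain, inertia is ~12 orders below
elastic forces. The constrained system is solved by Jacobi-preconditioned
conjugate gradients to a relative residual of 1e-8 (configurable). Stresses
are evaluated at element centroids; von Mises with the standard deviatoric
definition. Because the problem is linear with a single scalar load, one
solve at a 1 µm reference top displacement spans the whole cycle.

A consequence worth stating: under prescribed-displacement boundary
conditions the displacement field of a homogeneous linear-elastic body does
not depend on the magnitude of E at all; the group moduli affect stresses
but not kinematics, hence not the fluid problem.

## Fluid solver

Marker-and-cell (MAC) staggered finite differences on the pore + margin
phase: velocity components on cell faces, pressure in cell centers.
With µ = 85.5 Pa·s, v ~ 1 µm/s, L ~ 100 µm the Reynolds number is ~1e-9 and
inertia is dropped; each sample time is an independent Stokes solve. Wall
displacements (≤ 0.8 µm) are ≪ the 18 µm voxel, so the geometry is frozen
and walls contribute velocity only (small-perturbation assumption).

The study's “open boundary” is realized by designating the outermost voxel
layer of the margin as *pressure-reservoir* cells: pressure is prescribed
there, continuity is not enforced, and fluid crosses freely. This keeps the
saddle-point operator exactly symmetric, [[A, G], [Gᵀ, 0]], which MINRES
requires. Preconditioning: Jacobi on the velocity block and the Schur-scale
1/µ on the pressure block; the solver verifies momentum and continuity
residuals separately and warm-restarts until both meet tolerance.

The mean reservoir pressure is subtracted before solving (a constant shifts
the discrete pressure field exactly and leaves velocity untouched), so the
hydrostatic case — equal pressure on all six faces, static walls — yields an
*exactly* zero velocity field rather than solver-noise-small. This matters:
with the study's identical-phase pressures on all six faces, the
pressure-driven mode vanishes, the FSS time series is proportional to
|du/dt|, and its two per-cycle maxima at T/4 and 3T/4 tie exactly (the
reported peak is the first, T/4).

No-slip at solid walls uses prescribed face-normal velocities on interface
faces and mirrored ghost values (2·u_wall − u_f) for tangential components;
wall velocities are sampled from the FE displacement shape by trilinear
interpolation (interface points touch only solid nodes). FSS per wall face
is the magnitude of the tangential viscous traction: µ(∂v_t/∂n + ∂v_n/∂t)
with a one-sided difference at h/2 for the first term and neighbouring
wall-face values for the second. Verification: plane Couette is reproduced
to machine precision (the scheme is exact for linear profiles), square-duct
Poiseuille centreline to 0.3 % at 16 cells across, and the duct's mean wall
FSS matches the global force balance Δp·A/(L·P_wet) to 1e-9.

## Cycle orchestration

Superposition fast path (default): one unit solid solve, one wall-driven
Stokes mode (walls moving with the unit displacement shape), one
pressure-driven mode; every snapshot is an analytic rescaling by u(t),
du/dt(t), P(t). The stepwise path re-solves everything per sample time and
agrees with the fast path to < 1e-7 relative — this is both a speedup
(~n_steps×) and a strong correctness oracle. Default 20 steps per cycle;
a single cycle is simulated since the quasi-static problem is exactly
periodic. Peak timing uses quadratic interpolation around the maximum
sample, ties resolved to the first sample.

## Postprocessing and statistics

* Central crop: fraction 0.875 of the core edge (0.7-ish mm of a 0.8 mm
  cube); index rounding is nearest-integer with ties toward the lower index.
* Sections: voxel layers nearest 1/4, 1/2, 3/4 of the core height along the
  loading axis.
* FSS bands: half-open [low, high) at 0.1, 1, 3 Pa with (3, ∞) on top;
  proportions are count-weighted over interface faces (the voxel analogue of
  the study's surface nodes).
* Time-fraction-in-band: fraction of faces in band for strictly more than a
  given fraction (default 1/2) of sampled times.
* Summaries use population (n) SD and linear-interpolation quantiles; the SD
  convention is recorded in output metadata.
* Group comparison: tie-corrected Kruskal–Wallis (chi-square reference,
  K−1 df) with an exact-permutation option for the study's n = 3 per group,
  and Dunn's pairwise z tests on pooled ranks with Bonferroni adjustment
  (the post-hoc is switchable and named in outputs). Significance threshold
  P < 0.05, with a small-sample caveat attached.

## Problem sizes

Default experiment sizes were chosen so a complete verification cycle runs
on a laptop-class single core: the reference run uses a 48³ core (≈33 k
solid voxels, ≈100 k fluid cells; about half a minute for the three-solve
fast path), the fast-vs-stepwise cross-check a 16³ core, and the
multi-group direction check 24³ cores with six feasible seeds per level.
All sizes are parameters, not limits.

## Known limitations

* **BV/TV–FSS direction.** On this synthetic ensemble the crop-mean surface
  FSS *increases* with BV/TV (Spearman ρ ≈ +0.7 across the six group
  levels), opposite to the negative association reported for real scanned
  geometries. The mechanism is transparent: displacement-controlled loading
  fixes the wall kinematics regardless of modulus, so FSS scales like
  µ·u̇/d_pore, and pore size shrinks as BV/TV rises. Reproducing the
  negative direction appears to require architecture the isotropic GRF lacks
  — low-BV/TV bone as a sparse network of slender rods whose bending
  amplifies local wall motion and channels faster flow. Passing tests on
  this generator therefore validate the solvers and statistics, not the
  architectural mechanism; for that, segmented micro-CT masks should be
  supplied via `load_voxel_mask`.
* One-way coupling neglects fluid-on-solid feedback (strains ~5e-8 from
  ≤ 1 kPa fluid stresses on ≥ 11 GPa bone); monolithic FSI would recover a
  modulus dependence of the flow, but at this stress ratio it is far below
  the other model errors.
* No surface smoothing: voxel staircases bias local FSS up at edges; the
  wall-FSS discretization is first-order at walls, so absolute FSS values
  carry O(h) error even where the geometry is smooth.
* The lateral spring constant is so large that the faces are effectively
  fixed; the precise k (and its unit reading) is immaterial within several
  orders of magnitude.
* Marrow is treated as Newtonian at a single temperature; non-Newtonian
  rheology and fat-fraction heterogeneity are out of scope.
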