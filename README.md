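# marrowflow

Load-induced marrow flow and fluid shear stress (FSS) in trabecular bone.

Mechanical loading of cancellous bone drives the viscous marrow through the
pore network; the resulting wall shear stress on the trabecular surface is a
primary mechanobiological stimulus (in vitro, osteoblasts respond to FSS of
about 1–3 Pa, osteoclasts migrate to regions below ~0.1 Pa). `marrowflow`
simulates this stimulus for cube-shaped trabecular samples — synthetic
Gaussian-random-field geometries at a prescribed bone volume fraction
(BV/TV), or user-supplied segmented micro-CT masks — and computes the
surface FSS statistics used to compare experimental groups, for researchers
in bone mechanobiology and computational biomechanics.

## Model

One 0.8 mm voxel cube of bone (18 µm pitch) sits in a slightly larger box of
marrow. Over one loading cycle of period *T*:

* **Solid.** The bone phase is a uniform isotropic linear-elastic voxel
  micro-FE model (trilinear hexahedra). The bottom face is fixed, the top
  face carries the sinusoidal compressive displacement
  `u(t) = B/2 [sin(2π(t − T/4)/T) + 1]` (B = 0.8 µm, T = 1 s), and the four
  lateral faces rest on a spring foundation `T_t = −k (U_solid − U_0)` with
  k = 16×10⁹ N/mm² per mm — effectively rigid lateral support.
* **Fluid.** Marrow is Newtonian (µ = 85.5 Pa·s, ρ = 0.95 g/cm³). At these
  scales Re ≈ 10⁻⁹, so each instant is a quasi-static incompressible Stokes
  problem, µ∇²v = ∇p, ∇·v = 0, on a staggered (MAC) grid: no-slip walls
  moving with the solid surface velocity, and open outer boundaries at the
  normal pressure `P(t) = C/2 [sin(2π(t − T/4)/T) + 1]` (C = 667 Pa).
* **Coupling.** One-way (solid → fluid), quasi-static and linear, so the
  entire cycle is reconstructed from one unit solid solve plus two unit
  Stokes solves (wall-driven and pressure-driven modes).
* **Outputs.** Wall FSS = tangential part of the viscous traction
  µ(∇v + ∇vᵀ)·n per interface face and time; von Mises stress; velocity and
  pressure fields; central-crop summaries; FSS band proportions
  (<0.1, 0.1–1, 1–3, >3 Pa); time-fraction in the 1–3 Pa band; and
  Kruskal–Wallis + Dunn comparisons of per-sample statistics across the six
  study groups (control, diabetic, four verapamil doses, each with its own
  tissue modulus and BV/TV).

## Worked example

```python
from marrowflow import (GeometrySpec, LoadSpec, generate_trabecular,
                        material_for_group, run_cycle, peak_time)

dom = generate_trabecular(GeometrySpec(grid_n=48, bvtv_target=0.30, seed=1))
res = run_cycle(dom, material_for_group("CON"), LoadSpec(), n_steps=20)
print(f"wall faces: {res.interface.n_faces}")
print(f"peak mean surface FSS: {res.mean_fss.max():.3f} Pa")
print(f"peak time: {peak_time(res.times, res.mean_fss, 1.0):.3f} s")
```

prints

```
wall faces: 22324
peak mean surface FSS: 0.819 Pa
peak time: 0.250 s
```

The mean surface FSS peaks at t = T/4 = 0.25 s — the instant of maximal
compression *rate*, since the wall-driven Stokes mode scales with du/dt
while a spatially uniform outer pressure drives no flow at all (hydrostatic
equilibrium). The peak value (~0.8 Pa for this BV/TV 0.30 synthetic cube)
sits in the physiological sub-3-Pa range.

The same pipeline is scriptable from the shell:

```sh
marrowflow generate --config run.yaml --all-groups
marrowflow run --config run.yaml --out results/
marrowflow compare --results results_CON --results results_T2DM --out cmp.json
marrowflow report --compare-json cmp.json
```

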