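"""Orchestration of one loading cycle: solid solve -> wall velocities ->
fluid solve -> interface FSS time series.

Coupling is one-way (solid to fluid): fluid stresses (~Pa) are negligible
against solid stresses (~MPa), so no feedback iteration is needed.  Because
both subproblems are linear and quasi-static, the entire cycle is spanned by
three unit solves —

* one solid solve at unit top displacement (shape ``u_hat``),
* one Stokes solve with walls moving at ``u_hat`` per unit top velocity,
* one Stokes solve with unit outer pressure and static walls —

and every snapshot is a scaling of these by u(t), du/dt(t) and P(t).  The
stepwise path re-solves at every sample time and serves as a cross-check;
both must agree to solver tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .elasticity import (
    ElasticSystem,
    SolverError,
    SolidSolution,
    apply_solid_bcs,
    assemble_elasticity,
    nodal_displacement_grid,
    solve_solid,
)
from .geometry import VoxelDomain
from .materials import MaterialSpec
from .stokes import (
    FluidSolution,
    InterfaceFSS,
    StokesSystem,
    apply_fluid_bcs,
    assemble_stokes,
    solve_stokes,
    wall_shear_stress,
)
from .waveforms import (
    LoadSpec,
    displacement_rate,
    displacement_waveform,
    pressure_waveform,
)

__all__ = ["CycleResult", "run_cycle", "superposition_fast_path"]

_REF_TOP_UM = 1.0  # reference top displacement for the unit solid solve (um)


@dataclass
class CycleResult:
    """Fields and interface FSS over one loading cycle.

    ``times`` are the n_steps uniform sample times in [0, T).  ``interface``
    carries the per-face FSS series; ``mean_fss`` its face-average per time.
    Unit-mode fields allow any snapshot to be reconstructed.
    """

    times: np.ndarray
    interface: InterfaceFSS
    mean_fss: np.ndarray
    solid_unit: SolidSolution          # per _REF_TOP_UM of top displacement
    fluid_wall_mode: FluidSolution     # per 1 m/s of top velocity
    fluid_pressure_mode: FluidSolution  # per 1 Pa of outer pressure
    load: LoadSpec
    mat: MaterialSpec
    domain: VoxelDomain
    flux_balance_rel: float
    max_divergence: float

    def scale_factors(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(solid, wall-mode, pressure-mode) scalings at time(s) t."""
        s_solid = displacement_waveform(t, self.load) / _REF_TOP_UM
        s_wall = displacement_rate(t, self.load) * 1e-6  # um/s -> m/s
        s_pres = pressure_waveform(t, self.load)
        return s_solid, s_wall, s_pres

    def solid_at(self, t: float) -> SolidSolution:
        s, _, _ = self.scale_factors(t)
        u = self.solid_unit
        return SolidSolution(
            displacement=u.displacement * s,
            stress=u.stress * s,
            von_mises=u.von_mises * s,
            time=float(t),
            element_centroids=u.element_centroids,
            node_coords=u.node_coords,
        )

    def fluid_at(self, t: float) -> FluidSolution:
        _, sw, sp = self.scale_factors(t)
        w, p = self.fluid_wall_mode, self.fluid_pressure_mode
        return FluidSolution(
            velocity=[sw * a + sp * b for a, b in zip(w.velocity, p.velocity)],
            pressure=sw * w.pressure + sp * p.pressure,
            time=float(t),
        )

    def save(self, path) -> None:
        """Lossless round-trip serialization (npz + json sidecar)."""
        np.savez_compressed(
            path,
            times=self.times,
            fss=self.interface.fss,
            iface_axes=self.interface.axes,
            iface_normals=self.interface.normals,
            iface_points=self.interface.points,
            mean_fss=self.mean_fss,
            labels=self.domain.labels,
            solid_disp=self.solid_unit.displacement,
            solid_stress=self.solid_unit.stress,
            solid_vm=self.solid_unit.von_mises,
            solid_centroids=self.solid_unit.element_centroids,
            solid_nodes=self.solid_unit.node_coords,
            wall_vel=np.array(
                [v for v in self.fluid_wall_mode.velocity], dtype=object
            ),
            meta=json.dumps(
                {
                    "pitch": self.domain.pitch,
                    "margin_vox": self.domain.margin_vox,
                    "loading_axis": self.domain.loading_axis,
                    "flux_balance_rel": self.flux_balance_rel,
                    "max_divergence": self.max_divergence,
                }
            ),
            allow_pickle=True,
        )


def _wall_velocity_sampler(solid_sys: ElasticSystem, unit_sol: SolidSolution):
    """Sampler of the solid motion shape: um coords -> m/s per 1 m/s of top
    velocity (i.e. the dimensionless displacement shape u_hat)."""
    grid = nodal_displacement_grid(solid_sys, unit_sol) / _REF_TOP_UM
    pitch = solid_sys.domain.pitch

    def sample(points_um: np.ndarray) -> np.ndarray:
        coords = (np.asarray(points_um, dtype=float) / pitch).T
        out = np.empty((len(points_um), 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(grid[c], coords, order=1,
                                                mode="nearest")
        return out

    return sample


def _cycle_times(load: LoadSpec, n_steps: int) -> np.ndarray:
    if n_steps < 8:
        raise ValueError("n_steps must be >= 8 to resolve the waveform")
    return np.arange(n_steps) * load.T / n_steps


def superposition_fast_path(
    domain: VoxelDomain,
    mat: MaterialSpec,
    load: LoadSpec,
    n_steps: int = 20,
    rtol: float = 1e-8,
) -> CycleResult:
    """One solid solve + two Stokes mode solves, rescaled to all times."""
    times = _cycle_times(load, n_steps)
    solid_sys = assemble_elasticity(domain, mat)
    solid_sys.rtol = rtol
    # unit solid solve at the reference top displacement
    apply_solid_bcs(solid_sys, 0.0, load, u_top_um=_REF_TOP_UM)
    unit = solve_solid(solid_sys)
    sampler = _wall_velocity_sampler(solid_sys, unit)

    fluid_sys = assemble_stokes(domain, mat)
    fluid_sys.rtol = rtol
    apply_fluid_bcs(fluid_sys, pressure=0.0, wall_velocity=sampler)
    wall_mode = solve_stokes(fluid_sys)
    tau_w, _ = wall_shear_stress(wall_mode, fluid_sys)
    flux_rel = wall_mode.flux_balance_rel
    maxdiv = float(np.max(np.abs(wall_mode.divergence), initial=0.0))

    apply_fluid_bcs(fluid_sys, pressure=1.0)
    pres_mode = solve_stokes(fluid_sys)
    tau_p, _ = wall_shear_stress(pres_mode, fluid_sys)
    maxdiv = max(maxdiv, float(np.max(np.abs(pres_mode.divergence), initial=0.0)))

    _, sw, sp = _scales(load, times)
    tau_t = sw[None, :, None] * tau_w[:, None, :] + sp[None, :, None] * tau_p[:, None, :]
    fss = np.linalg.norm(tau_t, axis=2)  # (n_faces, n_times)

    iface = InterfaceFSS(
        axes=fluid_sys.wall_axes,
        normals=fluid_sys.iface.normals,
        points=fluid_sys.iface.points,
        fss=fss,
        times=times,
    )
    return CycleResult(
        times=times,
        interface=iface,
        mean_fss=fss.mean(axis=0),
        solid_unit=unit,
        fluid_wall_mode=wall_mode,
        fluid_pressure_mode=pres_mode,
        load=load,
        mat=mat,
        domain=domain,
        flux_balance_rel=flux_rel,
        max_divergence=maxdiv,
    )


def _scales(load: LoadSpec, times: np.ndarray):
    s_solid = displacement_waveform(times, load) / _REF_TOP_UM
    s_wall = displacement_rate(times, load) * 1e-6
    s_pres = pressure_waveform(times, load)
    return s_solid, s_wall, s_pres


def run_cycle(
    domain: VoxelDomain,
    mat: MaterialSpec,
    load: LoadSpec,
    n_steps: int = 20,
    method: str = "fast",
    rtol: float = 1e-8,
) -> CycleResult:
    """Simulate one loading cycle at n_steps uniform sample times.

    ``method="fast"`` uses the three-unit-solve superposition path;
    ``method="stepwise"`` re-solves solid and fluid at every time sample
    (the validation path — identical results to solver tolerance).
    """
    if method == "fast":
        return superposition_fast_path(domain, mat, load, n_steps, rtol)
    if method != "stepwise":
        raise ValueError(f"unknown method {method!r}")
    times = _cycle_times(load, n_steps)
    solid_sys = assemble_elasticity(domain, mat)
    solid_sys.rtol = rtol
    fluid_sys = assemble_stokes(domain, mat)
    fluid_sys.rtol = rtol

    fss_all = []
    flux_rel = 0.0
    maxdiv = 0.0
    unit = None
    for i, t in enumerate(times):
        try:
            apply_solid_bcs(solid_sys, t, load)
            sol_s = solve_solid(solid_sys)
            u_t = float(displacement_waveform(t, load))
            du_t = float(displacement_rate(t, load))
            if u_t <= 1e-12 * load.B:
                sampler = None  # u = 0 only where du/dt = 0: static walls
            else:
                # wall velocity = (du/dt / u) * instantaneous displacement
                grid_sampler = _wall_velocity_sampler_from(sol_s, solid_sys)
                factor = du_t / u_t * 1e-6  # um displacement -> m/s

                def sampler(pts, _s=grid_sampler, _r=factor):
                    return _s(pts) * _r

            apply_fluid_bcs(fluid_sys, pressure=float(pressure_waveform(t, load)),
                            wall_velocity=sampler)
            sol_f = solve_stokes(fluid_sys)
            tau, fss = wall_shear_stress(sol_f, fluid_sys)
            fss_all.append(fss)
            flux_rel = max(flux_rel, sol_f.flux_balance_rel)
            maxdiv = max(maxdiv, float(np.max(np.abs(sol_f.divergence),
                                              initial=0.0)))
            if unit is None and u_t > 1e-12 * load.B:
                s = _REF_TOP_UM / u_t
                unit = SolidSolution(
                    displacement=sol_s.displacement * s,
                    stress=sol_s.stress * s,
                    von_mises=sol_s.von_mises * s,
                    time=0.0,
                    element_centroids=sol_s.element_centroids,
                    node_coords=sol_s.node_coords,
                )
        except Exception as exc:
            raise type(exc)(f"time step {i} (t={t:.4f} s): {exc}") from exc
    fss = np.column_stack(fss_all)
    iface = InterfaceFSS(
        axes=fluid_sys.wall_axes,
        normals=fluid_sys.iface.normals,
        points=fluid_sys.iface.points,
        fss=fss,
        times=times,
    )
    # mode fields for parity with the fast path
    if unit is None:
        raise SolverError("no nonzero displacement sample in the cycle")
    apply_fluid_bcs(fluid_sys, pressure=0.0,
                    wall_velocity=_wall_velocity_sampler(solid_sys, unit))
    wall_mode = solve_stokes(fluid_sys)
    apply_fluid_bcs(fluid_sys, pressure=1.0)
    pres_mode = solve_stokes(fluid_sys)
    return CycleResult(
        times=times,
        interface=iface,
        mean_fss=fss.mean(axis=0),
        solid_unit=unit,
        fluid_wall_mode=wall_mode,
        fluid_pressure_mode=pres_mode,
        load=load,
        mat=mat,
        domain=domain,
        flux_balance_rel=flux_rel,
        max_divergence=maxdiv,
    )


def _wall_velocity_sampler_from(sol: SolidSolution, system: ElasticSystem):
    """Sampler of the instantaneous displacement field (um out per um in)."""
    grid = nodal_displacement_grid(system, sol)
    pitch = system.domain.pitch

    def sample(points_um: np.ndarray) -> np.ndarray:
        coords = (np.asarray(points_um, dtype=float) / pitch).T
        out = np.empty((len(points_um), 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(grid[c], coords, order=1,
                                                mode="nearest")
        return out

    return sample
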