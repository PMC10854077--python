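"""Stokes solver: analytic oracles (Couette, duct), conservation, linearity."""

import numpy as np
import pytest

from marrowflow.geometry import PORE, SOLID, VoxelDomain
from marrowflow.materials import MaterialSpec
from marrowflow.stokes import (
    apply_fluid_bcs,
    assemble_stokes,
    solve_stokes,
    wall_shear_stress,
)

PITCH = 18.0
H = PITCH * 1e-6


@pytest.fixture(scope="module")
def mat():
    return MaterialSpec()


def all_fluid_box(n=10):
    from marrowflow.geometry import MARGIN

    lab = np.full((n, n, n), MARGIN, dtype=np.int8)
    lab[1:-1, 1:-1, 1:-1] = PORE
    return VoxelDomain(labels=lab, pitch=PITCH, margin_vox=1)


def couette_domain(gap=16, nx=12, ny=12, wall=2):
    nz = gap + 2 * wall
    lab = np.full((nx, ny, nz), PORE, dtype=np.int8)
    lab[:, :, :wall] = SOLID
    lab[:, :, -wall:] = SOLID
    return VoxelDomain(labels=lab, pitch=PITCH, margin_vox=0), nz


def duct_domain(width=16, nx=24, wall=2):
    n_yz = width + 2 * wall
    lab = np.full((nx, n_yz, n_yz), SOLID, dtype=np.int8)
    lab[:, wall:wall + width, wall:wall + width] = PORE
    return VoxelDomain(labels=lab, pitch=PITCH, margin_vox=0)


class TestHydrostaticAndLinearity:
    def test_equal_pressure_static_walls_is_hydrostatic(self, mat):
        system = assemble_stokes(all_fluid_box(), mat)
        apply_fluid_bcs(system, pressure=667.0)
        sol = solve_stokes(system)
        assert max(np.abs(v).max() for v in sol.velocity) < 1e-12
        p = sol.pressure[system.interior]
        assert np.abs(p - 667.0).max() < 1e-6

    def test_zero_data_zero_solution(self, mat):
        system = assemble_stokes(all_fluid_box(), mat)
        apply_fluid_bcs(system, pressure=0.0)
        sol = solve_stokes(system)
        assert max(np.abs(v).max() for v in sol.velocity) == 0.0

    def test_superposition_in_boundary_data(self, mat):
        """v(aP, bV) = a v(P, 0) + b v(0, V) for the linear Stokes operator."""
        dom, nz = couette_domain(gap=8, nx=10, ny=10)
        system = assemble_stokes(dom, mat)
        U = 1e-6

        def wallv(pts):
            v = np.zeros((len(pts), 3))
            v[:, 0] = np.where(pts[:, 2] > (nz - 2) * PITCH - 1e-9, U, 0.0)
            return v

        def pres(pts):
            return np.where(pts[:, 0] < 5 * PITCH, 10.0, 0.0)

        apply_fluid_bcs(system, pressure=pres)
        vp = solve_stokes(system)
        apply_fluid_bcs(system, pressure=0.0, wall_velocity=wallv)
        vw = solve_stokes(system)

        def pres2(pts):
            return 2.0 * pres(pts)

        def wallv3(pts):
            return 3.0 * wallv(pts)

        apply_fluid_bcs(system, pressure=pres2, wall_velocity=wallv3)
        both = solve_stokes(system)
        scale = max(np.abs(both.velocity[0]).max(), 1e-300)
        for a in range(3):
            combo = 2.0 * vp.velocity[a] + 3.0 * vw.velocity[a]
            assert np.abs(both.velocity[a] - combo).max() < 1e-6 * scale


class TestCouette:
    def test_linear_profile_and_wall_fss(self, mat):
        dom, nz = couette_domain()
        system = assemble_stokes(dom, mat)
        U = 1e-6
        gap = 16 * H

        def wallv(pts):
            v = np.zeros((len(pts), 3))
            v[:, 0] = np.where(pts[:, 2] > (nz - 2) * PITCH - 1e-9, U, 0.0)
            return v

        apply_fluid_bcs(system, pressure=0.0, wall_velocity=wallv)
        sol = solve_stokes(system)
        prof = sol.velocity[0][6, 6, 2:-2]
        lin = (np.arange(16) + 0.5) / 16 * U
        assert np.abs(prof - lin).max() < 1e-9 * U

        _, fss = wall_shear_stress(sol, system)
        # central faces (away from the open x/y edges of this slab fixture)
        pos = system.wall_pos
        sel = ((system.wall_axes == 2)
               & (pos[:, 0] >= 2) & (pos[:, 0] < 10)
               & (pos[:, 1] >= 2) & (pos[:, 1] < 10))
        expected = mat.mu_fluid * U / gap
        assert np.abs(fss[sel] - expected).max() / expected < 0.01

    def test_couette_unit_fss(self, mat):
        """U/h chosen so mu U / h = 1 Pa gives FSS = 1 Pa on both walls."""
        dom, nz = couette_domain()
        system = assemble_stokes(dom, mat)
        gap = 16 * H
        U = gap / mat.mu_fluid  # shear rate U/gap = 1/mu

        def wallv(pts):
            v = np.zeros((len(pts), 3))
            v[:, 0] = np.where(pts[:, 2] > (nz - 2) * PITCH - 1e-9, U, 0.0)
            return v

        apply_fluid_bcs(system, pressure=0.0, wall_velocity=wallv)
        sol = solve_stokes(system)
        _, fss = wall_shear_stress(sol, system)
        pos = system.wall_pos
        for zplane in (2, nz - 2):
            sel = ((system.wall_axes == 2) & (pos[:, 2] == zplane)
                   & (pos[:, 0] >= 2) & (pos[:, 0] < 10)
                   & (pos[:, 1] >= 2) & (pos[:, 1] < 10))
            assert fss[sel].mean() == pytest.approx(1.0, rel=0.01)

    def test_doubling_wall_velocity_doubles_flow(self, mat):
        dom, nz = couette_domain(gap=8, nx=8, ny=8)
        system = assemble_stokes(dom, mat)

        def mk(u):
            def wallv(pts):
                v = np.zeros((len(pts), 3))
                v[:, 0] = np.where(pts[:, 2] > (nz - 2) * PITCH - 1e-9, u, 0.0)
                return v
            return wallv

        apply_fluid_bcs(system, pressure=0.0, wall_velocity=mk(1e-6))
        a = solve_stokes(system)
        apply_fluid_bcs(system, pressure=0.0, wall_velocity=mk(2e-6))
        b = solve_stokes(system)
        scale = np.abs(a.velocity[0]).max()
        for c in range(3):
            assert np.abs(b.velocity[c] - 2 * a.velocity[c]).max() < 1e-6 * scale

    def test_interior_speed_bounded_by_wall_speed(self, mat):
        """Wall-driven Couette: no interior amplification beyond the data."""
        dom, nz = couette_domain()
        system = assemble_stokes(dom, mat)
        U = 1e-6

        def wallv(pts):
            v = np.zeros((len(pts), 3))
            v[:, 0] = np.where(pts[:, 2] > (nz - 2) * PITCH - 1e-9, U, 0.0)
            return v

        apply_fluid_bcs(system, pressure=0.0, wall_velocity=wallv)
        sol = solve_stokes(system)
        assert max(np.abs(v).max() for v in sol.velocity) <= 1.1 * U


@pytest.fixture(scope="module")
def duct_solution(mat):
    dom = duct_domain()
    system = assemble_stokes(dom, mat)
    dp = 1000.0

    def pres(pts):
        return np.where(pts[:, 0] < 12 * PITCH, dp, 0.0)

    apply_fluid_bcs(system, pressure=pres)
    return system, solve_stokes(system), dp


class TestDuct:
    @staticmethod
    def series_umax(G, mu, a, terms=80):
        s = 0.0
        for n in range(1, terms, 2):
            bn = n * np.pi / (2 * a)
            s += ((-1) ** ((n - 1) // 2)) / n**3 * (1 - 1 / np.cosh(bn * a))
        return 16 * G * a**2 / (mu * np.pi**3) * s

    def test_centreline_velocity_vs_series(self, mat, duct_solution):
        system, sol, dp = duct_solution
        G = dp / (23 * H)  # gradient between reservoir cell centers
        umax = self.series_umax(G, mat.mu_fluid, 8 * H)
        centre = sol.velocity[0][12, 10, 10]
        assert centre == pytest.approx(umax, rel=0.05)

    def test_mean_wall_fss_force_balance(self, mat, duct_solution):
        """Mean wall FSS equals dp*A/(L*P_wet) by global momentum balance."""
        system, sol, dp = duct_solution
        _, fss = wall_shear_stress(sol, system)
        mid = (system.wall_pos[:, 0] >= 6) & (system.wall_pos[:, 0] < 18)
        G = dp / (23 * H)
        A = (16 * H) ** 2
        P_wet = 4 * 16 * H
        assert fss[mid].mean() == pytest.approx(G * A / P_wet, rel=1e-3)

    def test_incompressibility_and_flux_balance(self, duct_solution):
        system, sol, dp = duct_solution
        vmax = max(np.abs(v).max() for v in sol.velocity)
        # divergence residual per cell, relative to the gross flux scale u/h
        assert np.abs(sol.divergence).max() < 1e-6 * vmax / system.h
        assert sol.flux_balance_rel < 1e-6


class TestFssProperties:
    def test_zero_flow_zero_fss(self, mat):
        system = assemble_stokes(all_fluid_box(), mat)
        apply_fluid_bcs(system, pressure=667.0)
        sol = solve_stokes(system)
        # no wall faces in an all-fluid box
        tau, fss = wall_shear_stress(sol, system)
        assert fss.size == 0

    def test_fss_nonnegative_on_trabecular_flow(self, mat, cycle_small):
        assert (cycle_small.interface.fss >= 0).all()
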