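"""Quasi-static incompressible Stokes flow in the marrow pore space.

Marrow is ~85 Pa s viscous; at the reported velocities (um/s) and pore sizes
(~100 um) the Reynolds number is ~1e-9, so inertia is dropped entirely and
each time instant is an independent Stokes problem

    mu lap(v) - grad(p) = 0,   div(v) = 0

on the pore + margin phase, driven by (i) no-slip walls moving with the solid
surface velocity and (ii) a uniform normal pressure on the six open outer
faces.  Wall displacements (<= 0.8 um) are far below the voxel pitch, so the
geometry is held fixed and walls contribute velocity only.

Discretization: marker-and-cell (MAC) staggered finite differences on the
voxel lattice — velocity components on cell faces, pressure at cell centers.
The open outer boundary is realized by designating the outermost voxel layer
of the fluid margin as pressure-reservoir cells: their pressure is prescribed
(Dirichlet) and continuity is not enforced there, which lets volume enter and
leave freely while keeping the discrete saddle-point operator symmetric.
The symmetric system [[A, G], [G^T, 0]] is solved by preconditioned MINRES
(Jacobi on the velocity block, 1/mu scaling on the pressure Schur block).

Wall fluid shear stress (FSS) is the magnitude of the tangential part of the
viscous traction mu (grad v + grad v^T) n on each solid-fluid interface face,
evaluated with one-sided differences at the wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, minres

from .geometry import MARGIN, SOLID, VoxelDomain
from .elasticity import SolverError
from .materials import MaterialSpec
from .waveforms import LoadSpec, pressure_waveform

__all__ = [
    "FluidSolution",
    "InterfaceFSS",
    "StokesSystem",
    "assemble_stokes",
    "apply_fluid_bcs",
    "solve_stokes",
    "wall_shear_stress",
    "static_walls",
]

_EYE = np.eye(3, dtype=int)


def static_walls(points_um: np.ndarray) -> np.ndarray:
    """Wall-velocity sampler for rigid, motionless walls."""
    return np.zeros((len(points_um), 3))


@dataclass
class InterfaceFSS:
    """Solid-fluid interface faces with per-face FSS time series.

    ``axes[i]`` is the face-normal axis, ``normals[i]`` the outward (solid to
    fluid) unit normal, ``points[i]`` the face center in um.  ``fss`` has
    shape (n_faces, n_times) in Pa; ``times`` in s.
    """

    axes: np.ndarray
    normals: np.ndarray
    points: np.ndarray
    fss: np.ndarray | None = None
    times: np.ndarray | None = None

    @property
    def n_faces(self) -> int:
        return len(self.axes)


@dataclass
class FluidSolution:
    """MAC velocity/pressure state at one time.

    ``velocity[a]`` holds the a-component on axis-a faces (shape = cells + 1
    along a), m/s, with prescribed wall values filled in.  ``pressure`` is per
    cell (Pa, reservoir cells carry their boundary value; solid cells 0).
    """

    velocity: list
    pressure: np.ndarray
    time: float
    divergence: np.ndarray = field(default=None, repr=False)  # per interior cell
    flux_balance_rel: float = 0.0

    def cell_speed(self, interior_mask: np.ndarray) -> np.ndarray:
        """Cell-center speed magnitude (m/s) for the given cells."""
        comps = []
        for a in range(3):
            v = self.velocity[a]
            lo = v[tuple(slice(0, -1) if d == a else slice(None) for d in range(3))]
            hi = v[tuple(slice(1, None) if d == a else slice(None) for d in range(3))]
            comps.append(0.5 * (lo + hi))
        speed = np.sqrt(sum(c**2 for c in comps))
        return speed[interior_mask]


class StokesSystem:
    """Assembled MAC Stokes operator for the fluid phase of one domain.

    Geometry-only: boundary values enter through :func:`apply_fluid_bcs`,
    so one assembly serves every time step and superposition mode.
    """

    def __init__(self, domain: VoxelDomain, mat: MaterialSpec):
        domain.validate()
        self.domain = domain
        self.mat = mat
        self.h = domain.pitch * 1e-6  # m
        lab = domain.labels
        shape = lab.shape
        self.shape = shape
        fluid = lab != SOLID
        reservoir = np.zeros(shape, dtype=bool)
        for a in range(3):
            sl0 = [slice(None)] * 3
            sl0[a] = 0
            reservoir[tuple(sl0)] = True
            sl0[a] = shape[a] - 1
            reservoir[tuple(sl0)] = True
        reservoir &= fluid
        interior = fluid & ~reservoir
        if not interior.any():
            raise ValueError("no interior fluid cells")
        comp, ncomp = ndimage.label(
            fluid, structure=ndimage.generate_binary_structure(3, 1)
        )
        if len(np.unique(comp[fluid])) != 1:
            raise ValueError(
                "fluid phase is not a single connected component; "
                "run cleanup_connectivity first"
            )
        self.fluid, self.reservoir, self.interior = fluid, reservoir, interior
        solid = lab == SOLID

        # ---- face classification per axis --------------------------------
        self.face_shape = [tuple(s + (1 if d == a else 0) for d, s in enumerate(shape))
                           for a in range(3)]
        self.unknown = []
        self.wallmask = []
        self.uid = []
        n_u = 0
        wall_axes, wall_pos, wall_sign = [], [], []
        for a in range(3):
            L = tuple(slice(0, -1) if d == a else slice(None) for d in range(3))
            R = tuple(slice(1, None) if d == a else slice(None) for d in range(3))
            fS = self.face_shape[a]
            unk = np.zeros(fS, dtype=bool)
            wal = np.zeros(fS, dtype=bool)
            inner = tuple(slice(1, -1) if d == a else slice(None) for d in range(3))
            fl, fr = fluid[L], fluid[R]
            il, ir = interior[L], interior[R]
            sl_, sr_ = solid[L], solid[R]
            unk[inner] = fl & fr & (il | ir)
            wal[inner] = (sl_ & fr) | (fl & sr_)
            self.unknown.append(unk)
            self.wallmask.append(wal)
            ids = np.full(fS, -1, dtype=np.int64)
            nf = int(unk.sum())
            ids[unk] = np.arange(n_u, n_u + nf)
            n_u += nf
            self.uid.append(ids)
            wp = np.argwhere(wal)
            wall_axes.append(np.full(len(wp), a))
            wall_pos.append(wp)
            # fluid on +a side -> outward normal +a
            fr_at = np.zeros(fS, dtype=bool)
            fr_at[inner] = fr
            wall_sign.append(np.where(fr_at[wal], 1, -1))
        self.n_u = n_u
        self.wall_axes = np.concatenate(wall_axes)
        self.wall_pos = np.concatenate(wall_pos, axis=0)
        self.wall_sign = np.concatenate(wall_sign)

        # pressure numbering over interior cells
        self.pid = np.full(shape, -1, dtype=np.int64)
        self.n_p = int(interior.sum())
        self.pid[interior] = np.arange(self.n_p)
        self.cell_res_flat = None  # filled during assembly

        self._assemble(solid)
        self.iface = InterfaceFSS(
            axes=self.wall_axes,
            normals=self.wall_sign[:, None] * _EYE[self.wall_axes],
            points=self.face_centers_um(self.wall_axes, self.wall_pos),
        )
        # BC state
        self.rhs: np.ndarray | None = None
        self.wall_values: list | None = None
        self.wall_sampler = None
        self.p_res_value: np.ndarray | float = 0.0
        self.rtol = 1e-8
        self.maxiter = 60000

    # -- helpers ------------------------------------------------------------

    def face_centers_um(self, axes: np.ndarray, pos: np.ndarray) -> np.ndarray:
        c = (pos + 0.5) * self.domain.pitch
        c[np.arange(len(axes)), axes] = pos[np.arange(len(axes)), axes] * self.domain.pitch
        return c

    def _assemble(self, solid: np.ndarray) -> None:
        mu = self.mat.mu_fluid
        h = self.h
        cf = mu / h**2
        shape = self.shape
        rows, cols, data = [], [], []
        # RHS recipes
        wk_rows, wk_coef, wk_axis, wk_flat = [], [], [], []       # known wall faces
        gh_rows, gh_coef, gh_pts, gh_comp = [], [], [], []        # both-solid ghosts
        pr_rows, pr_coef, pr_flat = [], [], []                    # reservoir pressures

        res_flat_ids = np.full(shape, -1, dtype=np.int64)
        res_cells = np.argwhere(self.reservoir)
        res_flat_ids[tuple(res_cells.T)] = np.arange(len(res_cells))
        self.res_cells = res_cells

        for a in range(3):
            unk = self.unknown[a]
            wal = self.wallmask[a]
            ids = self.uid[a]
            fS = self.face_shape[a]
            P = np.argwhere(unk)  # face positions
            rowid = ids[unk]
            # momentum: Laplacian neighbours
            for b in range(3):
                for s in (-1, 1):
                    Q = P + s * _EYE[b]
                    inb = np.all((Q >= 0) & (Q < np.array(fS)), axis=1)
                    # classify in-bounds neighbours
                    Qc = np.clip(Q, 0, np.array(fS) - 1)
                    qflat = np.ravel_multi_index(tuple(Qc.T), fS)
                    is_unk = inb & unk.flat[qflat]
                    is_wal = inb & wal.flat[qflat]
                    if b == a:
                        is_ghost = np.zeros(len(P), dtype=bool)
                    else:
                        # cells of neighbour face q: (q - e_a, q); both solid?
                        CL = Q - _EYE[a]
                        okc = np.all((CL >= 0) & (Q < np.array(shape)), axis=1) & inb
                        CLc = np.clip(CL, 0, np.array(shape) - 1)
                        Qcc = np.clip(Q, 0, np.array(shape) - 1)
                        both = (solid[tuple(CLc.T)] & solid[tuple(Qcc.T)]) & okc
                        is_ghost = both & ~is_unk & ~is_wal
                    # unknown neighbour: -cf off-diagonal, +cf diagonal
                    m = is_unk
                    if m.any():
                        rows.append(rowid[m])
                        cols.append(ids.flat[qflat[m]])
                        data.append(np.full(m.sum(), -cf))
                        rows.append(rowid[m])
                        cols.append(rowid[m])
                        data.append(np.full(m.sum(), cf))
                    # wall neighbour (known face value)
                    m = is_wal
                    if m.any():
                        rows.append(rowid[m])
                        cols.append(rowid[m])
                        data.append(np.full(m.sum(), cf))
                        wk_rows.append(rowid[m])
                        wk_coef.append(np.full(m.sum(), cf))
                        wk_axis.append(np.full(m.sum(), a))
                        wk_flat.append(qflat[m])
                    # both-solid ghost: no-slip at the half-way wall plane
                    m = is_ghost
                    if m.any():
                        rows.append(rowid[m])
                        cols.append(rowid[m])
                        data.append(np.full(m.sum(), 2 * cf))
                        mid = 0.5 * (self.face_centers_um(np.full(m.sum(), a), P[m])
                                     + self.face_centers_um(np.full(m.sum(), a), Q[m]))
                        gh_rows.append(rowid[m])
                        gh_coef.append(np.full(m.sum(), 2 * cf))
                        gh_pts.append(mid)
                        gh_comp.append(np.full(m.sum(), a))
                    # else: drop (zero-gradient: outer box or reservoir pair)
            # pressure gradient: cells L = p - e_a, R = p
            for side, sgn in ((-1, -1.0), (0, 1.0)):
                Cc = P + side * _EYE[a]
                cflat = np.ravel_multi_index(tuple(Cc.T), shape)
                p_unb = self.pid.flat[cflat]
                m = p_unb >= 0
                if m.any():
                    rows.append(rowid[m])
                    cols.append(self.n_u + p_unb[m])
                    data.append(np.full(m.sum(), sgn / h))
                mres = ~m & self.reservoir.flat[cflat]
                if mres.any():
                    pr_rows.append(rowid[mres])
                    pr_coef.append(np.full(mres.sum(), -sgn / h))
                    pr_flat.append(res_flat_ids.flat[cflat[mres]])
        # continuity rows, assembled as G^T (= -divergence) so the saddle
        # matrix [[A, G], [G^T, 0]] is symmetric; known wall fluxes to RHS
        cw_rows, cw_coef, cw_axis, cw_flat = [], [], [], []
        IC = np.argwhere(self.interior)
        crow = self.pid[tuple(IC.T)]
        for a in range(3):
            fS = self.face_shape[a]
            for upper, sgn in ((1, 1.0), (0, -1.0)):
                F = IC + upper * _EYE[a]
                fflat = np.ravel_multi_index(tuple(F.T), fS)
                fid = self.uid[a].flat[fflat]
                m = fid >= 0
                if m.any():
                    rows.append(self.n_u + crow[m])
                    cols.append(fid[m])
                    data.append(np.full(m.sum(), -sgn / h))
                mw = ~m & self.wallmask[a].flat[fflat]
                if mw.any():
                    cw_rows.append(self.n_u + crow[mw])
                    cw_coef.append(np.full(mw.sum(), sgn / h))
                    cw_axis.append(np.full(mw.sum(), a))
                    cw_flat.append(fflat[mw])

        n = self.n_u + self.n_p
        self.M = coo_matrix(
            (np.concatenate(data),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
        cat = lambda xs, dt=float: (np.concatenate(xs).astype(dt) if xs
                                    else np.empty(0, dtype=dt))
        self.wk = (cat(wk_rows, np.int64), cat(wk_coef), cat(wk_axis, np.int64),
                   cat(wk_flat, np.int64))
        cw = (cat(cw_rows, np.int64), cat(cw_coef), cat(cw_axis, np.int64),
              cat(cw_flat, np.int64))
        self.wk = tuple(np.concatenate([self.wk[i], cw[i]]) for i in range(4))
        self.gh = (cat(gh_rows, np.int64), cat(gh_coef),
                   (np.concatenate(gh_pts) if gh_pts else np.empty((0, 3))),
                   cat(gh_comp, np.int64))
        self.pr = (cat(pr_rows, np.int64), cat(pr_coef), cat(pr_flat, np.int64))
        # Jacobi / Schur preconditioner diagonal
        diag = np.asarray(self.M.diagonal()).copy()
        diag[self.n_u:] = 1.0 / self.mat.mu_fluid
        self.precond_diag = diag


def assemble_stokes(domain: VoxelDomain, mat: MaterialSpec) -> StokesSystem:
    """Build the MAC Stokes operator for the fluid phase."""
    return StokesSystem(domain, mat)


def apply_fluid_bcs(
    system: StokesSystem,
    t: float | None = None,
    load: LoadSpec | None = None,
    wall_velocity=None,
    pressure=None,
) -> StokesSystem:
    """Set boundary data: outer pressure and wall velocities.

    ``pressure`` may be a scalar (Pa, applied to every reservoir cell), a
    callable of cell-center coordinates (um), or None, in which case
    ``pressure_waveform(t, load)`` is used.  ``wall_velocity`` is a callable
    mapping (n, 3) um coordinates to (n, 3) m/s velocities (default: static
    walls).
    """
    if pressure is None:
        if t is None or load is None:
            raise ValueError("either pressure or (t, load) must be given")
        pressure = float(pressure_waveform(t, load))
    if wall_velocity is None:
        wall_velocity = static_walls
    # per-axis prescribed wall-face values (normal component)
    wall_values = []
    for a in range(3):
        arr = np.zeros(system.face_shape[a])
        wp = np.argwhere(system.wallmask[a])
        if len(wp):
            pts = system.face_centers_um(np.full(len(wp), a), wp)
            arr[tuple(wp.T)] = wall_velocity(pts)[:, a]
        wall_values.append(arr)
    system.wall_values = wall_values
    system.wall_sampler = wall_velocity

    res_pts = (system.res_cells + 0.5) * system.domain.pitch
    if callable(pressure):
        p_res = np.asarray(pressure(res_pts), dtype=float)
    else:
        p_res = np.full(len(system.res_cells), float(pressure))
    system.p_res_value = p_res
    # A constant added to the reservoir pressure shifts the discrete pressure
    # field by exactly that constant and leaves velocity untouched; solving
    # for the deviation from the mean makes the uniform-pressure case (the
    # hydrostatic limit) exactly zero instead of solver-noise small.
    p_gauge = float(p_res.mean()) if len(p_res) else 0.0
    system.p_gauge = p_gauge
    p_res = p_res - p_gauge

    rhs = np.zeros(system.n_u + system.n_p)
    rows, coef, ax, flat = system.wk
    if len(rows):
        vals = np.empty(len(rows))
        for a in range(3):
            m = ax == a
            vals[m] = wall_values[a].flat[flat[m]]
        np.add.at(rhs, rows, coef * vals)
    rows, coef, pts, comp = system.gh
    if len(rows):
        v = wall_velocity(pts)
        np.add.at(rhs, rows, coef * v[np.arange(len(rows)), comp])
    rows, coef, flat = system.pr
    if len(rows):
        np.add.at(rhs, rows, coef * p_res[flat])
    system.rhs = rhs
    system.time = 0.0 if t is None else float(t)
    return system


def solve_stokes(system: StokesSystem) -> FluidSolution:
    """MINRES solve of the saddle-point system; verifies momentum and
    continuity residuals, warm-restarting until both meet ``system.rtol``."""
    if system.rhs is None:
        raise RuntimeError("apply_fluid_bcs must be called before solve_stokes")
    b = system.rhs
    n_u = system.n_u
    M = system.M
    diag = system.precond_diag
    Minv = LinearOperator(M.shape, matvec=lambda x: x / diag)

    x = np.zeros_like(b)
    bnorm = np.linalg.norm(b)
    if bnorm > 0:
        # residual scales: momentum rows ~ mu/h^2 * velocity, continuity ~ u/h
        scale_u = max(np.linalg.norm(b[:n_u]), bnorm * system.h)
        rtol_k = system.rtol * 1e-2
        for _ in range(5):
            x, info = minres(M, b, x0=x, rtol=max(rtol_k, 1e-14),
                             maxiter=system.maxiter, M=Minv)
            r = b - M @ x
            # natural velocity scale: solution, wall data, or pressure-driven
            wall_scale = max(np.max(np.abs(v), initial=0.0)
                             for v in system.wall_values)
            p_scale = np.max(np.abs(system.p_res_value), initial=0.0)
            vel_scale = max(np.max(np.abs(x[:n_u]), initial=0.0), wall_scale,
                            p_scale * system.h / system.mat.mu_fluid, 1e-300)
            mom_ok = np.linalg.norm(r[:n_u]) <= system.rtol * scale_u
            div_ok = np.max(np.abs(r[n_u:]), initial=0.0) <= (
                system.rtol * vel_scale / system.h * 10
            )
            if mom_ok and div_ok:
                break
            rtol_k *= 1e-2
        else:
            raise SolverError(
                f"Stokes MINRES stagnated: |r_mom|={np.linalg.norm(r[:n_u]):.2e}, "
                f"max|div|={np.max(np.abs(r[n_u:])):.2e}"
            )

    velocity = []
    for a in range(3):
        arr = np.zeros(system.face_shape[a])
        unk = system.unknown[a]
        arr[unk] = x[system.uid[a][unk]]
        arr[system.wallmask[a]] = system.wall_values[a][system.wallmask[a]]
        velocity.append(arr)
    pressure = np.zeros(system.shape)
    pressure[system.interior] = x[n_u:] + system.p_gauge
    pressure[tuple(system.res_cells.T)] = system.p_res_value

    div = (M @ x - b)[n_u:] if bnorm > 0 else np.zeros(system.n_p)
    sol = FluidSolution(velocity=velocity, pressure=pressure, time=system.time,
                        divergence=div)
    sol.flux_balance_rel = _flux_balance(system, sol)
    return sol


def _flux_balance(system: StokesSystem, sol: FluidSolution) -> float:
    """Relative mismatch between outer-face outflow and wall-displaced volume.

    Summing every continuity equation telescopes interior fluxes away, so the
    net flux crossing into the reservoir must balance the volume rate swept
    by the moving walls; the return value is that mismatch relative to the
    gross (absolute) flux through both boundaries.
    """
    net = 0.0
    gross = 0.0
    for a in range(3):
        unk = system.unknown[a]
        wal = system.wallmask[a]
        # every boundary face of the interior region, signed outward
        P = np.argwhere(unk | wal)
        L = P - _EYE[a]
        Lint = system.interior[tuple(L.T)]
        Rint = system.interior[tuple(P.T)]
        v = sol.velocity[a][tuple(P.T)]
        out_hi = Lint & ~Rint  # +a flux leaves the interior region
        out_lo = Rint & ~Lint  # -a side boundary, outward is -a
        net += v[out_hi].sum() - v[out_lo].sum()
        gross += np.abs(v[out_hi]).sum() + np.abs(v[out_lo]).sum()
    if gross == 0:
        return 0.0
    return abs(net) / gross


def wall_shear_stress(
    sol: FluidSolution,
    system: StokesSystem,
    mat: MaterialSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tangential viscous traction on every wall face.

    Returns ``(tau, fss)`` where ``tau`` is (n_faces, 2) signed tangential
    traction components (Pa) along the two axes != face normal (ascending
    order) and ``fss = |tau|``.  One-sided differences at the wall: the
    du_t/dn term uses the adjacent fluid-cell-center tangential velocity at
    h/2, the du_n/dt term central differences of neighbouring wall-face
    normal velocities.  Signed components superpose linearly across load
    modes; the magnitude is taken afterwards.
    """
    mu = (mat or system.mat).mu_fluid
    h = system.h
    axes = system.wall_axes
    pos = system.wall_pos
    sign = system.wall_sign
    nf = len(axes)
    tau = np.zeros((nf, 2))
    wall_pts = system.iface.points
    wall_vel = (system.wall_sampler or static_walls)(wall_pts)  # (nf, 3) m/s
    shape = system.shape
    for a in range(3):
        sel = np.flatnonzero(axes == a)
        if sel.size == 0:
            continue
        P = pos[sel]
        sg = sign[sel]
        fluid_cell = P.copy()
        lower = sg < 0  # fluid on -a side is cell P - e_a
        fluid_cell[lower] -= _EYE[a]
        tgt = [b for b in range(3) if b != a]
        for j, b in enumerate(tgt):
            vb = sol.velocity[b]
            lo = fluid_cell
            hi = fluid_cell + _EYE[b]
            v_cell = 0.5 * (vb[tuple(lo.T)] + vb[tuple(hi.T)])
            dvt_dn = sg * (v_cell - wall_vel[sel, b]) / (h / 2.0)
            # d v_n / d x_b from neighbouring wall-face normal velocities
            va = sol.velocity[a]
            wmask = system.wallmask[a]
            Qp = P + _EYE[b]
            Qm = P - _EYE[b]
            okp = np.all((Qp >= 0) & (Qp < np.array(system.face_shape[a])), axis=1)
            okm = np.all(Qm >= 0, axis=1)
            okp &= wmask[tuple(np.clip(Qp, 0, np.array(system.face_shape[a]) - 1).T)]
            okm &= wmask[tuple(np.clip(Qm, 0, np.array(system.face_shape[a]) - 1).T)]
            vp = np.where(okp, va[tuple(np.clip(Qp, 0, np.array(system.face_shape[a]) - 1).T)], 0.0)
            vm = np.where(okm, va[tuple(np.clip(Qm, 0, np.array(system.face_shape[a]) - 1).T)], 0.0)
            v0 = va[tuple(P.T)]
            both = okp & okm
            dvn_dt = np.zeros(len(P))
            dvn_dt[both] = (vp[both] - vm[both]) / (2 * h)
            onlyp = okp & ~okm
            dvn_dt[onlyp] = (vp[onlyp] - v0[onlyp]) / h
            onlym = okm & ~okp
            dvn_dt[onlym] = (v0[onlym] - vm[onlym]) / h
            tau[sel, j] = mu * (dvt_dn + sg * dvn_dt)
    fss = np.linalg.norm(tau, axis=1)
    return tau, fss
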