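"""Voxel micro-finite-element linear elasticity for the solid phase.

Each solid voxel becomes one trilinear (8-node) hexahedral element with
uniform isotropic properties — the standard micro-FE approach for segmented
micro-CT bone.  The quasi-static assumption holds because the 1 Hz loading
period vastly exceeds the elastic response time at ~0.1% strain, so each time
instant is an independent linear solve; in fact the whole cycle is one unit
solve rescaled by the displacement waveform.

Boundary conditions on the solid core: bottom face fully fixed, top face
prescribed displacement along the loading axis (in-plane components free),
and a spring foundation (Robin term) on the four lateral faces acting, by
default, on the face-normal displacement component.

Units: geometry in um is converted to m internally; displacements are
reported in um and stresses in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .geometry import SOLID, VoxelDomain
from .materials import MaterialSpec
from .waveforms import LoadSpec, displacement_waveform

__all__ = [
    "SolverError",
    "SolidSolution",
    "ElasticSystem",
    "assemble_elasticity",
    "apply_solid_bcs",
    "solve_solid",
    "von_mises",
    "hex_stiffness",
]


class SolverError(RuntimeError):
    """Raised when a sparse solve fails to reach the requested residual."""


# local node offsets of a voxel element, x fastest
_OFFS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]]
)


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Gradients dN_l/dxi (8, 3) of trilinear shape functions on [0,1]^3."""
    g = np.empty((8, 3))
    for l, (a, b, c) in enumerate(_OFFS):
        fx = xi[0] if a else 1 - xi[0]
        fy = xi[1] if b else 1 - xi[1]
        fz = xi[2] if c else 1 - xi[2]
        g[l, 0] = (1.0 if a else -1.0) * fy * fz
        g[l, 1] = fx * (1.0 if b else -1.0) * fz
        g[l, 2] = fx * fy * (1.0 if c else -1.0)
    return g


def _bmat(xi: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 24) on the unit cube, Voigt order
    (xx, yy, zz, xy, yz, zx)."""
    g = _shape_gradients(xi)
    B = np.zeros((6, 24))
    for l in range(8):
        c = 3 * l
        B[0, c + 0] = g[l, 0]
        B[1, c + 1] = g[l, 1]
        B[2, c + 2] = g[l, 2]
        B[3, c + 0] = g[l, 1]
        B[3, c + 1] = g[l, 0]
        B[4, c + 1] = g[l, 2]
        B[4, c + 2] = g[l, 1]
        B[5, c + 0] = g[l, 2]
        B[5, c + 2] = g[l, 0]
    return B


def _cmat(E: float, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix in Voigt notation."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def hex_stiffness(nu: float, E: float = 1.0, h: float = 1.0) -> np.ndarray:
    """24x24 stiffness matrix of a cube voxel element of edge h.

    Full 2x2x2 Gauss integration; scales as E*h from the unit-cube matrix.
    """
    C = _cmat(1.0, nu)
    gp = 0.5 + np.array([-1, 1]) / (2 * np.sqrt(3.0))
    K = np.zeros((24, 24))
    for x in gp:
        for y in gp:
            for z in gp:
                B = _bmat(np.array([x, y, z]))
                K += 0.125 * B.T @ C @ B
    return E * h * K


@dataclass
class SolidSolution:
    """Displacement/stress state of the solid phase at one time.

    displacement : (n_nodes, 3) um, ordered as ``system.node_ids``.
    stress : (n_elems, 6) MPa in Voigt order (xx, yy, zz, xy, yz, zx).
    von_mises : (n_elems,) MPa.  element_centroids : (n_elems, 3) um.
    """

    displacement: np.ndarray
    stress: np.ndarray
    von_mises: np.ndarray
    time: float
    element_centroids: np.ndarray
    node_coords: np.ndarray


def von_mises(stress) -> np.ndarray:
    """Von Mises equivalent stress from Voigt components (..., 6)."""
    s = np.asarray(stress, dtype=float)
    sxx, syy, szz, sxy, syz, szx = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )


class ElasticSystem:
    """Assembled voxel-FE operator over the solid phase of one domain.

    Reusable across time steps: geometry and material fix the stiffness; only
    the prescribed top displacement changes with t.
    """

    def __init__(self, domain: VoxelDomain, mat: MaterialSpec):
        domain.validate()
        self.domain = domain
        self.mat = mat
        self.h = domain.pitch * 1e-6  # m
        lab = domain.labels
        solid = lab == SOLID
        if not solid.any():
            raise ValueError("solid phase is empty")
        ncomp = ndimage.label(solid, structure=ndimage.generate_binary_structure(3, 1))[1]
        if ncomp != 1:
            raise SolverError(
                f"solid phase has {ncomp} face-connected components; "
                "run cleanup_connectivity first"
            )
        self.vox = np.argwhere(solid)  # (ne, 3) cell indices
        nodes_shape = tuple(s + 1 for s in lab.shape)
        self.nodes_shape = nodes_shape
        conn_multi = self.vox[:, None, :] + _OFFS[None, :, :]
        gids = np.ravel_multi_index(
            tuple(conn_multi.reshape(-1, 3).T), nodes_shape
        ).reshape(-1, 8)
        self.node_ids, conn = np.unique(gids, return_inverse=True)
        self.conn = conn.reshape(-1, 8).astype(np.int64)
        self.node_multi = np.column_stack(
            np.unravel_index(self.node_ids, nodes_shape)
        )  # (n_nodes, 3) node grid indices
        self.n_nodes = len(self.node_ids)
        self.ndof = 3 * self.n_nodes
        self.Ke = hex_stiffness(mat.nu, E=mat.E_pa, h=self.h)
        self.K = self._assemble()
        # BC state, set by apply_solid_bcs
        self.fixed_dofs: np.ndarray | None = None
        self.fixed_vals: np.ndarray | None = None
        self.robin_diag: np.ndarray | None = None
        self.load: LoadSpec | None = None
        self.time: float = 0.0
        self.rtol = 1e-8
        self.maxiter = 20000

    def _assemble(self) -> csr_matrix:
        edofs = (3 * self.conn[:, :, None] + np.arange(3)).reshape(-1, 24)
        ne = edofs.shape[0]
        rows = np.broadcast_to(edofs[:, :, None], (ne, 24, 24)).ravel()
        cols = np.broadcast_to(edofs[:, None, :], (ne, 24, 24)).ravel()
        data = np.tile(self.Ke.ravel(), ne)
        K = coo_matrix((data, (rows, cols)), shape=(self.ndof, self.ndof))
        return K.tocsr()

    # -- boundary-condition helpers -------------------------------------

    def _core_node_planes(self) -> tuple[int, int]:
        m = self.domain.margin_vox
        gn = self.domain.grid_n
        return m, m + gn

    def node_dof(self, node_rows: np.ndarray, comp: int) -> np.ndarray:
        return 3 * node_rows + comp

    def element_centroids_um(self) -> np.ndarray:
        return (self.vox + 0.5) * self.domain.pitch

    def node_coords_um(self) -> np.ndarray:
        return self.node_multi * self.domain.pitch


def assemble_elasticity(domain: VoxelDomain, mat: MaterialSpec) -> ElasticSystem:
    """Build the voxel-FE stiffness operator for the solid phase."""
    return ElasticSystem(domain, mat)


def apply_solid_bcs(
    system: ElasticSystem,
    t: float,
    load: LoadSpec,
    bottom: str = "fixed",
    spring_components: str = "normal",
    u_top_um: float | None = None,
) -> ElasticSystem:
    """Constrain the assembled system for time t.

    Bottom core face: fully fixed (``bottom="fixed"``) or roller
    (``bottom="roller"``: loading-axis component only, for verification
    against free-expansion closed forms).  Top core face: prescribed
    displacement ``u(t)`` along the loading axis, in-plane free.  Lateral
    core faces: spring foundation of stiffness ``load.k_si`` per unit area,
    lumped to face nodes, acting on the normal component by default
    (``spring_components="all"`` pins all three).
    """
    ax = system.domain.loading_axis
    lo, hi = system._core_node_planes()
    nm = system.node_multi
    bottom_nodes = np.flatnonzero(nm[:, ax] == lo)
    top_nodes = np.flatnonzero(nm[:, ax] == hi)
    if bottom_nodes.size == 0 or top_nodes.size == 0:
        raise SolverError(
            "solid does not reach the top/bottom loading planes; "
            "geometry is pathological for this loading axis"
        )
    if u_top_um is None:
        u_top_um = float(displacement_waveform(t, load))
    u_t = u_top_um * 1e-6  # m

    fixed, vals = [], []
    if bottom == "fixed":
        for c in range(3):
            fixed.append(system.node_dof(bottom_nodes, c))
            vals.append(np.zeros(bottom_nodes.size))
    elif bottom == "roller":
        fixed.append(system.node_dof(bottom_nodes, ax))
        vals.append(np.zeros(bottom_nodes.size))
    else:
        raise ValueError(f"unknown bottom BC {bottom!r}")
    fixed.append(system.node_dof(top_nodes, ax))
    vals.append(np.full(top_nodes.size, u_t))
    system.fixed_dofs = np.concatenate(fixed)
    system.fixed_vals = np.concatenate(vals)

    # Robin (spring) diagonal on lateral core faces, k per area lumped
    robin = np.zeros(system.ndof)
    if load.k_si > 0:
        m = system.domain.margin_vox
        gn = system.domain.grid_n
        h = system.h
        kA4 = load.k_si * h * h / 4.0
        lateral_axes = [a for a in range(3) if a != ax]
        id_grid = np.full(system.nodes_shape, -1, dtype=np.int64)
        id_grid[tuple(nm.T)] = np.arange(system.n_nodes)
        for a in lateral_axes:
            for side, vox_plane, node_plane in (
                (0, m, m), (1, m + gn - 1, m + gn)
            ):
                face_vox = system.vox[system.vox[:, a] == vox_plane]
                if face_vox.size == 0:
                    continue
                # 4 nodes of each voxel face lying on the lateral plane
                offs = _OFFS[_OFFS[:, a] == (0 if side == 0 else 1)]
                fn = (face_vox[:, None, :] + offs[None, :, :]).reshape(-1, 3)
                rows = id_grid[tuple(fn.T)]
                comps = [a] if spring_components == "normal" else [0, 1, 2]
                for c in comps:
                    np.add.at(robin, system.node_dof(rows, c), kA4)
    system.robin_diag = robin
    system.load = load
    system.time = float(t)
    return system


def solve_solid(system: ElasticSystem) -> SolidSolution:
    """Solve the constrained system by Jacobi-preconditioned CG.

    Converges to a relative residual of ``system.rtol``; element stresses are
    evaluated at element centroids.
    """
    if system.fixed_dofs is None:
        raise RuntimeError("apply_solid_bcs must be called before solve_solid")
    K = system.K
    robin = system.robin_diag
    ndof = system.ndof
    free = np.ones(ndof, dtype=bool)
    free[system.fixed_dofs] = False
    u = np.zeros(ndof)
    u[system.fixed_dofs] = system.fixed_vals

    rhs = -(K @ u)
    b = rhs[free]
    Kff = K[free][:, free]
    if robin is not None and robin.any():
        Kff = Kff + csr_matrix(
            (robin[free], (np.arange(free.sum()), np.arange(free.sum()))),
            shape=Kff.shape,
        )
    diag = Kff.diagonal()
    if (diag <= 0).any():
        raise SolverError("non-positive diagonal; system is singular")
    Minv = LinearOperator(Kff.shape, matvec=lambda x: x / diag)
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        uf = np.zeros(free.sum())
    else:
        uf, info = cg(Kff, b, rtol=system.rtol, atol=0.0, M=Minv,
                      maxiter=system.maxiter)
        if info != 0:
            res = np.linalg.norm(b - Kff @ uf) / bnorm
            raise SolverError(f"CG failed (info={info}), rel residual {res:.2e}")
    u[free] = uf

    # centroid stresses
    h = system.h
    Bc = _bmat(np.array([0.5, 0.5, 0.5])) / h  # physical gradient
    C = _cmat(system.mat.E_pa, system.mat.nu)
    edofs = (3 * system.conn[:, :, None] + np.arange(3)).reshape(-1, 24)
    ue = u[edofs]  # (ne, 24)
    strain = ue @ Bc.T
    stress_pa = strain @ C.T
    vm = von_mises(stress_pa)
    return SolidSolution(
        displacement=u.reshape(-1, 3) * 1e6,
        stress=stress_pa * 1e-6,
        von_mises=vm * 1e-6,
        time=system.time,
        element_centroids=system.element_centroids_um(),
        node_coords=system.node_coords_um(),
    )


def nodal_displacement_grid(system: ElasticSystem, sol: SolidSolution) -> np.ndarray:
    """Scatter nodal displacement onto the full node grid, um, zeros off-solid.

    Shape (3, nx+1, ny+1, nz+1); used to sample wall velocities for the
    fluid solver (trilinear interpolation on solid faces touches only solid
    nodes, so the off-solid zeros are never mixed in).
    """
    grid = np.zeros((3,) + system.nodes_shape)
    idx = tuple(system.node_multi.T)
    for c in range(3):
        grid[c][idx] = sol.displacement[:, c]
    return grid
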