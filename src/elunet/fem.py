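"""Small linear-elastostatic forward solver on regular hexahedral meshes.

One trilinear 8-node element per voxel, 2x2x2 Gauss integration, with a
(possibly different) 6x6 Voigt stiffness per element.  Boundary
conditions reproduce the compression experiments the phantoms emulate:
a uniform normal traction on the loaded face, a frictionless (roller)
support on the opposite face — zero normal displacement, zero tangential
traction — free lateral faces, and in-plane rigid-body modes pinned at
two corner nodes of the support face.

Strains are evaluated at element (voxel) centers, which is where the
inverse problem's fields live.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import BoundaryTractions, VolumetricField, strain_field

__all__ = ["solve_forward", "FEMResult"]

# local node offsets of the trilinear hexahedron
_OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
    (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1),
])
# natural coordinates of the nodes
_XI_N = 2.0 * _OFFSETS - 1.0


def _shape_gradients(xi: np.ndarray, spacing) -> np.ndarray:
    """(8, 3) physical gradients dN_n/dx at natural point xi."""
    hx, hy, hz = spacing
    g = np.empty((8, 3))
    for n in range(8):
        sx, sy, sz = _XI_N[n]
        fx, fy, fz = (1 + sx * xi[0]) / 2, (1 + sy * xi[1]) / 2, (1 + sz * xi[2]) / 2
        g[n] = (sx * fy * fz / hx, fx * sy * fz / hy, fx * fy * sz / hz)
    return g


def _b_matrix(xi: np.ndarray, spacing) -> np.ndarray:
    """(6, 24) strain-displacement matrix, engineering-shear rows, Voigt
    order (xx, yy, zz, xy, yz, xz); dof order (node, component)."""
    g = _shape_gradients(xi, spacing)
    B = np.zeros((6, 24))
    for n in range(8):
        dx, dy, dz = g[n]
        c = 3 * n
        B[0, c + 0] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c + 0], B[3, c + 1] = dy, dx
        B[4, c + 1], B[4, c + 2] = dz, dy
        B[5, c + 0], B[5, c + 2] = dz, dx
    return B


class FEMResult:
    def __init__(self, strain: VolumetricField, displacement: np.ndarray,
                 reaction_imbalance: float):
        self.strain = strain
        self.displacement = displacement          # (3, nodes_x, nodes_y, nodes_z)
        self.reaction_imbalance = reaction_imbalance


def solve_forward(stiffness: np.ndarray, spacing, bc: BoundaryTractions,
                  rtol: float = 1e-9) -> FEMResult:
    """Solve static equilibrium for per-voxel stiffness (nx, ny, nz, 6, 6).

    Returns voxel-center strains (tensor shear components), the nodal
    displacement field and the relative global force-balance error
    (reaction sum on the support face vs applied load).
    """
    stiffness = np.asarray(stiffness, dtype=float)
    nx, ny, nz = stiffness.shape[:3]
    hx, hy, hz = spacing
    n_nodes = (nx + 1) * (ny + 1) * (nz + 1)
    ndof = 3 * n_nodes

    # element stiffness, vectorized over all elements
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    Bs = np.stack([
        _b_matrix(np.array([gx, gy, gz]), spacing)
        for gx in gauss for gy in gauss for gz in gauss
    ])                                              # (8, 6, 24)
    detJw = hx * hy * hz / 8.0
    C = stiffness.reshape(-1, 6, 6)
    Ke = np.einsum("gai,eab,gbj->eij", Bs, C, Bs) * detJw   # (E, 24, 24)

    # connectivity: global node index of each element's 8 nodes
    ex, ey, ez = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ex, ey, ez = ex.ravel(), ey.ravel(), ez.ravel()
    nodes = np.stack([
        ((ex + dx) * (ny + 1) + (ey + dy)) * (nz + 1) + (ez + dz)
        for dx, dy, dz in _OFFSETS
    ], axis=1)                                      # (E, 8)
    dofs = (3 * nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)

    rows = np.broadcast_to(dofs[:, :, None], Ke.shape).ravel()
    cols = np.broadcast_to(dofs[:, None, :], Ke.shape).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    # consistent nodal loads for the uniform tractions on all loaded faces
    f = np.zeros(ndof)
    areas = {0: hy * hz, 1: hx * hz, 2: hx * hy}
    applied_force = np.zeros(3)
    max_face_force = 0.0
    for fname, fc in bc.faces.items():
        if fc.kind != "loaded" or fc.normal_traction == 0.0:
            continue
        axis = "xyz".index(fname[0])
        sign = 1.0 if fname[1] == "+" else -1.0
        face_elems = {"-": 0, "+": [nx, ny, nz][axis] - 1}[fname[1]]
        sel = [ex, ey, ez][axis] == face_elems
        face_offset = 0 if fname[1] == "-" else 1
        face_nodes = nodes[sel][:, _OFFSETS[:, axis] == face_offset]  # (Ef, 4)
        # traction vector = traction * outward normal; one quarter of the
        # element-face area per node (consistent load of a constant traction)
        load = fc.normal_traction * sign * areas[axis] / 4.0
        np.add.at(f, 3 * face_nodes.ravel() + axis, load)
        face_force = fc.normal_traction * sign * areas[axis] * sel.sum()
        applied_force[axis] += face_force
        max_face_force = max(max_face_force, abs(face_force))

    # Dirichlet set: zero normal displacement on each frictionless face,
    # plus corner pins killing the remaining rigid-body modes
    grid_idx = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                           np.arange(nz + 1), indexing="ij")
    node_ids = np.arange(n_nodes)
    fixed: set[int] = set()

    def node_at(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    support_faces = [name for name, fc in bc.faces.items()
                     if fc.kind == "frictionless"]
    for support_face in support_faces:
        s_axis = "xyz".index(support_face[0])
        s_plane = 0 if support_face[1] == "-" else [nx, ny, nz][s_axis]
        on_face = grid_idx[s_axis].ravel() == s_plane
        fixed.update((3 * node_ids[on_face] + s_axis).tolist())
    if support_faces:
        s_axis = "xyz".index(support_faces[0][0])
        s_plane = 0 if support_faces[0][1] == "-" else [nx, ny, nz][s_axis]
        inplane = [a for a in range(3) if a != s_axis]
        corner = [0, 0, 0]
        corner[s_axis] = s_plane
        c0 = node_at(*corner)
        corner2 = list(corner)
        corner2[inplane[0]] = [nx, ny, nz][inplane[0]]
        c1 = node_at(*corner2)
        fixed.update(3 * c0 + a for a in inplane)   # in-plane translations
        fixed.add(3 * c1 + inplane[1])              # in-plane rotation
    else:
        # pure-traction problem (self-equilibrated loads): standard 3-2-1
        # pinning of the six rigid modes
        c0 = node_at(0, 0, 0)
        cx = node_at(nx, 0, 0)
        cy = node_at(0, ny, 0)
        fixed.update(3 * c0 + a for a in range(3))
        fixed.update((3 * cx + 1, 3 * cx + 2, 3 * cy + 2))
    free = np.array(sorted(set(range(ndof)) - fixed))

    Kff = K[free][:, free]
    u = np.zeros(ndof)
    if len(free) <= 200_000:
        u[free] = spla.spsolve(Kff.tocsc(), f[free])
    else:
        sol, info = spla.cg(Kff, f[free], rtol=rtol, maxiter=20_000,
                            M=sp.diags(1.0 / Kff.diagonal()))
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
        u[free] = sol
    resid = np.linalg.norm(Kff @ u[free] - f[free])
    if resid > max(rtol, 1e-8) * max(np.linalg.norm(f[free]), 1e-30):
        raise RuntimeError(f"forward solve residual too large: {resid:.3e}")

    # global force balance: reactions at all constrained dofs must cancel
    # the applied load component-wise
    reactions = K @ u - f
    fixed_arr = np.array(sorted(fixed))
    react_force = np.zeros(3)
    for a in range(3):
        react_force[a] = reactions[fixed_arr[fixed_arr % 3 == a]].sum()
    # normalize by the largest single-face load so that self-equilibrated
    # (pure traction) cases do not divide by a vanishing net force
    scale_f = max(max_face_force, 1e-30)
    imbalance = np.abs(react_force + applied_force).max() / scale_f

    # voxel-center strains
    Bc = _b_matrix(np.zeros(3), spacing)            # (6, 24)
    ue = u[dofs]                                    # (E, 24)
    eps_voigt = ue @ Bc.T                           # engineering shears
    eps_voigt[:, 3:] *= 0.5                         # tensor components
    strain = strain_field(eps_voigt.T.reshape((6, nx, ny, nz)), spacing)
    u_field = u.reshape(nx + 1, ny + 1, nz + 1, 3).transpose(3, 0, 1, 2)
    return FEMResult(strain, u_field, float(imbalance))
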