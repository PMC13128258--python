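"""Physics loss terms and their analytic gradients.

The inversion minimizes three families of mean-squared residuals over
the volume, all in nondimensional units:

* constitutive: ``C(params) eps_voigt - sigma_net`` per voxel, with a
  trainable self-adaptive spatial weight field;
* static equilibrium: the finite-difference divergence of the network's
  stress output;
* boundary: mismatch between the stress output's face tractions and the
  prescribed face conditions (loaded / frictionless / free), with
  trainable per-face weight maps.

Both constitutive forms are *linear* in the material-parameter outputs:
isotropic stress is ``Lam * (A eps) + M * (Bm eps)`` and the rotated
transversely isotropic stress is ``sum_k c_k * (B^T E_k B) eps`` with
the Bond matrix B fixed by the known fiber orientation.  The per-voxel
coefficient tensors are precomputed once, so each training step costs a
handful of elementwise products — and the loss gradients with respect
to every network output are exact.

Self-adaptive weights are parameterized as ``w = s**2`` (non-negative by
construction) and updated by gradient *ascent*, so they grow wherever
residuals persist and stay put where the physics is already satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import (
    bond_matrix_batch,
    euler_rotation_batch,
    ti_stiffness_basis,
)
from .fields import (
    BoundaryTractions,
    VolumetricField,
    _COMP_INDEX,
    _face_slice,
    apply_derivative,
    strain_to_voigt,
)

__all__ = [
    "LossBreakdown",
    "AdaptiveWeights",
    "ConstitutiveIso",
    "ConstitutiveTI",
    "equilibrium_loss",
    "BoundaryLoss",
    "update_adaptive_weights",
    "TotalLossIso",
    "TotalLossTI",
]


@dataclass
class LossBreakdown:
    constitutive: float
    equilibrium: float
    boundary: float
    per_loading: list["LossBreakdown"] = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.constitutive + self.equilibrium + self.boundary


class AdaptiveWeights:
    """Trainable spatial weights: one volume for the constitutive loss,
    one map per face for the boundary loss; ``w = s**2 >= 0`` with s
    initialized to one."""

    def __init__(self, grid_shape: tuple[int, int, int], dtype=np.float64):
        self.s_const = np.ones(grid_shape, dtype=dtype)
        self.g_const = np.zeros(grid_shape, dtype=dtype)
        self.s_face: dict[str, np.ndarray] = {}
        self.g_face: dict[str, np.ndarray] = {}
        for fname in ("x-", "x+", "y-", "y+", "z-", "z+"):
            axis = "xyz".index(fname[0])
            fshape = tuple(n for a, n in enumerate(grid_shape) if a != axis)
            self.s_face[fname] = np.ones(fshape, dtype=dtype)
            self.g_face[fname] = np.zeros(fshape, dtype=dtype)

    @property
    def const(self) -> np.ndarray:
        return self.s_const ** 2

    def face(self, fname: str) -> np.ndarray:
        return self.s_face[fname] ** 2

    def zero_grad(self) -> None:
        self.g_const[...] = 0.0
        for g in self.g_face.values():
            g[...] = 0.0


def update_adaptive_weights(w: AdaptiveWeights, lr: float) -> AdaptiveWeights:
    """One gradient-ascent step on the accumulated weight gradients."""
    w.s_const += lr * w.g_const
    for fname, g in w.g_face.items():
        w.s_face[fname] += lr * g
    return w


# ---------------------------------------------------------------------------
# constitutive residuals (precomputed linear coefficient tensors)

# dC/dLam and dC/dM for the isotropic stiffness in Voigt form
_A_LAM = np.zeros((6, 6))
_A_LAM[:3, :3] = 1.0
_B_MU = np.diag([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])


class ConstitutiveIso:
    """Isotropic constitutive residual r = Lam*(A eps) + M*(Bm eps) - sigma."""

    def __init__(self, strain: VolumetricField, dtype=np.float64):
        self.grid_shape = strain.grid_shape
        self.n = int(np.prod(self.grid_shape))
        eps = strain_to_voigt(strain)                       # (N, 6)
        self.a = np.ascontiguousarray(eps @ _A_LAM.T, dtype=dtype)
        self.b = np.ascontiguousarray(eps @ _B_MU.T, dtype=dtype)

    def residual(self, lam: np.ndarray, mu: np.ndarray,
                 sigma: np.ndarray) -> np.ndarray:
        """(N,) params and (N, 6) stress -> (N, 6) residual."""
        return lam[:, None] * self.a + mu[:, None] * self.b - sigma

    def loss_and_grads(self, lam, mu, sigma, weights: AdaptiveWeights):
        """Returns (loss, d/dlam, d/dmu, d/dsigma) and accumulates the
        weight gradient; all flat shapes ((N,), (N,), (N, 6))."""
        r = self.residual(lam, mu, sigma)
        w = weights.const.reshape(-1)
        r2 = np.einsum("nk,nk->n", r, r)
        scale = 1.0 / (6.0 * self.n)
        loss = float(scale * (w * r2).sum())
        wr = (2.0 * scale) * w[:, None] * r
        dlam = np.einsum("nk,nk->n", wr, self.a)
        dmu = np.einsum("nk,nk->n", wr, self.b)
        weights.g_const += (2.0 * scale) * (
            weights.s_const * r2.reshape(self.grid_shape))
        return loss, dlam, dmu, -wr


class ConstitutiveTI:
    """Transversely isotropic residual r = sum_k c_k G_k - sigma with
    G_k = B^T E_k (B eps) precomputed per voxel from the known fiber
    orientation and the loading's strain field."""

    def __init__(self, strain: VolumetricField, orientation: VolumetricField,
                 dtype=np.float64):
        self.grid_shape = strain.grid_shape
        self.n = int(np.prod(self.grid_shape))
        eps = strain_to_voigt(strain)                       # (N, 6)
        psi, theta, phi = (orientation.values[i].reshape(-1) for i in range(3))
        T = euler_rotation_batch(psi, theta, phi)           # (N, 3, 3)
        B = bond_matrix_batch(T)                            # (N, 6, 6)
        basis = ti_stiffness_basis()                        # (5, 6, 6)
        v = np.einsum("nij,nj->ni", B, eps)                 # B eps
        Ev = np.einsum("kij,nj->nki", basis, v)             # E_k (B eps)
        G = np.einsum("nij,nki->njk", B, Ev)                # B^T E_k (B eps)
        self.G = np.ascontiguousarray(G, dtype=dtype)       # (N, 6, 5)

    def residual(self, c: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """(N, 5) params and (N, 6) stress -> (N, 6) residual."""
        return np.einsum("njk,nk->nj", self.G, c) - sigma

    def loss_and_grads(self, c, sigma, weights: AdaptiveWeights):
        r = self.residual(c, sigma)
        w = weights.const.reshape(-1)
        r2 = np.einsum("nk,nk->n", r, r)
        scale = 1.0 / (6.0 * self.n)
        loss = float(scale * (w * r2).sum())
        wr = (2.0 * scale) * w[:, None] * r
        dc = np.einsum("nj,njk->nk", wr, self.G)
        weights.g_const += (2.0 * scale) * (
            weights.s_const * r2.reshape(self.grid_shape))
        return loss, dc, -wr


# ---------------------------------------------------------------------------
# equilibrium

_DIV_TERMS = [(i, j, _COMP_INDEX[i, j]) for i in range(3) for j in range(3)]


def equilibrium_loss(sigma: np.ndarray, spacing) -> tuple[float, np.ndarray]:
    """Mean squared FD divergence of a (6, nx, ny, nz) stress array;
    returns (loss, d(loss)/d(sigma)) via the adjoint stencils."""
    grid_shape = sigma.shape[1:]
    res = np.zeros((3,) + grid_shape)
    for i, j, comp in _DIV_TERMS:
        res[i] += apply_derivative(sigma[comp], j, spacing[j])
    n_entries = 3.0 * np.prod(grid_shape)
    loss = float((res ** 2).sum() / n_entries)
    dsigma = np.zeros_like(sigma, dtype=float)
    coeff = 2.0 / n_entries
    for i, j, comp in _DIV_TERMS:
        dsigma[comp] += coeff * apply_derivative(res[i], j, spacing[j],
                                                 transpose=True)
    return loss, dsigma


# ---------------------------------------------------------------------------
# boundary conditions


class BoundaryLoss:
    """Weighted mismatch between face tractions of the stress output and
    the prescribed conditions.

    Per face the constrained components are: loaded -> normal equals the
    prescribed traction and both shears vanish; frictionless -> shears
    vanish (the normal reaction is unknown); free -> all three vanish.
    """

    def __init__(self, bc: BoundaryTractions, grid_shape):
        self.grid_shape = tuple(grid_shape)
        self.terms = []      # (face, comp_channel, target, slice)
        for fname, fc in bc.faces.items():
            axis, idx = _face_slice(fname, self.grid_shape)
            others = [a for a in range(3) if a != axis]
            comps = []
            if fc.kind in ("loaded", "free"):
                target = fc.normal_traction if fc.kind == "loaded" else 0.0
                comps.append((_COMP_INDEX[axis, axis], target))
            for o in others:                     # shears vanish in all kinds
                comps.append((_COMP_INDEX[axis, o], 0.0))
            for comp, target in comps:
                self.terms.append((fname, comp, target, idx))
        self.n_entries = float(
            sum(np.prod([n for a, n in enumerate(self.grid_shape)
                         if a != "xyz".index(f[0])])
                for f, _, _, _ in self.terms))

    def loss_and_grads(self, sigma: np.ndarray, weights: AdaptiveWeights):
        loss = 0.0
        dsigma = np.zeros_like(sigma, dtype=float)
        scale = 1.0 / self.n_entries
        for fname, comp, target, idx in self.terms:
            w = weights.face(fname)
            mis = sigma[comp][idx] - target
            loss += scale * float((w * mis ** 2).sum())
            dsigma[comp][idx] += (2.0 * scale) * w * mis
            weights.g_face[fname] += (2.0 * scale) * (
                weights.s_face[fname] * mis ** 2)
        return loss, dsigma


# ---------------------------------------------------------------------------
# assembled totals


def _fd_spacing(spacing) -> tuple[float, ...]:
    """Voxel-normalized spacing for the training-loss FD operators.

    Dividing by the smallest voxel size makes the equilibrium residual
    O(1) per voxel instead of O(1/h), so the three loss families
    compete on comparable gradient scales during optimization (the
    zero set — divergence-free stress — is unchanged because the axis
    ratios are preserved).
    """
    m = min(spacing)
    return tuple(h / m for h in spacing)


class TotalLossIso:
    """Constitutive + equilibrium + boundary loss for one isotropic
    problem, with gradients w.r.t. the 8-channel network output."""

    def __init__(self, strain: VolumetricField, bc: BoundaryTractions):
        self.const = ConstitutiveIso(strain)
        self.bound = BoundaryLoss(bc, strain.grid_shape)
        self.spacing = _fd_spacing(strain.spacing)
        self.grid_shape = strain.grid_shape

    def __call__(self, outputs: np.ndarray, weights: AdaptiveWeights):
        """outputs: (8, nx, ny, nz) = (Lam, M, six stresses).

        Returns (LossBreakdown, d(loss)/d(outputs)).  Weight gradients
        are recomputed from scratch on every call.
        """
        weights.zero_grad()
        lam = outputs[0].reshape(-1).astype(np.float64)
        mu = outputs[1].reshape(-1).astype(np.float64)
        sigma_flat = outputs[2:8].reshape(6, -1).T.astype(np.float64)
        lc, dlam, dmu, dsig_c = self.const.loss_and_grads(
            lam, mu, sigma_flat, weights)
        sigma_vol = np.asarray(outputs[2:8], dtype=np.float64)
        le, dsig_e = equilibrium_loss(sigma_vol, self.spacing)
        lb, dsig_b = self.bound.loss_and_grads(sigma_vol, weights)
        d_out = np.empty((8,) + self.grid_shape)
        d_out[0] = dlam.reshape(self.grid_shape)
        d_out[1] = dmu.reshape(self.grid_shape)
        d_out[2:8] = (dsig_c.T.reshape((6,) + self.grid_shape)
                      + dsig_e + dsig_b)
        return LossBreakdown(lc, le, lb), d_out


class TotalLossTI:
    """Mean over the X/Y/Z loadings of per-loading totals, TI mode.

    Gradients are returned for the 5-channel parameter output (summed
    over loadings) and for each loading's 6-channel stress output.
    """

    def __init__(self, strains, bcs, orientation: VolumetricField,
                 min_loadings: int = 2):
        if len(strains) != len(bcs):
            raise ValueError("need one BC set per loading")
        if len(strains) < min_loadings:
            raise ValueError(
                f"{len(strains)} loading(s) under-determine the five TI "
                "parameters; at least two independent loadings are required"
            )
        self.grid_shape = strains[0].grid_shape
        self.spacing = _fd_spacing(strains[0].spacing)
        self.const = [ConstitutiveTI(s, orientation) for s in strains]
        self.bound = [BoundaryLoss(b, s.grid_shape)
                      for s, b in zip(strains, bcs)]
        self.n_load = len(strains)

    def per_loading(self, loading: int, c_flat: np.ndarray, sigma: np.ndarray,
                    weights: AdaptiveWeights):
        """Loss and gradients of one loading (no 1/n_loadings factor).

        ``c_flat`` is (N, 5); ``sigma`` is the (6, grid) stress output.
        Returns (LossBreakdown, d/dc_flat, d/dsigma).  Weight gradients
        accumulate across loadings; the caller rescales to the mean.
        """
        const, bound = self.const[loading], self.bound[loading]
        sig64 = np.asarray(sigma, dtype=np.float64)
        sig_flat = sig64.reshape(6, -1).T
        lc, dc, dsig_c = const.loss_and_grads(c_flat, sig_flat, weights)
        le, dsig_e = equilibrium_loss(sig64, self.spacing)
        lb, dsig_b = bound.loss_and_grads(sig64, weights)
        dsig = dsig_c.T.reshape(sig64.shape) + dsig_e + dsig_b
        return LossBreakdown(lc, le, lb), dc, dsig

    def __call__(self, c_out: np.ndarray, sigma_outs, weights: AdaptiveWeights):
        """c_out: (5, grid); sigma_outs: list of (6, grid) per loading.

        Returns (LossBreakdown, d/dc_out, [d/dsigma_l ...]); the
        breakdown's components are means over loadings.
        """
        weights.zero_grad()
        c_flat = c_out.reshape(5, -1).T.astype(np.float64)
        inv = 1.0 / self.n_load
        dc_total = np.zeros_like(c_flat)
        dsigs, parts = [], []
        for l, sig in enumerate(sigma_outs):
            part, dc, dsig = self.per_loading(l, c_flat, sig, weights)
            parts.append(part)
            dc_total += inv * dc
            dsigs.append(inv * dsig)
        mean = LossBreakdown(
            float(np.mean([p.constitutive for p in parts])),
            float(np.mean([p.equilibrium for p in parts])),
            float(np.mean([p.boundary for p in parts])),
            per_loading=parts,
        )
        # per-loading calls accumulated weight gradients for the summed
        # loss; rescale to the mean
        weights.g_const *= inv
        for g in weights.g_face.values():
            g *= inv
        d_c = dc_total.T.reshape((5,) + self.grid_shape)
        return mean, d_c, dsigs
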