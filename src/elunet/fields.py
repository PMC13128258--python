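"""Volumetric tensor-field containers and grid operators.

Fields live on regular voxel-centered grids as ``(C, nx, ny, nz)``
arrays with physical spacing ``(hx, hy, hz)``.  Strain and stress fields
carry exactly six channels in the Voigt order (xx, yy, zz, xy, yz, xz);
the shear channels store *tensor* components, which are doubled into
engineering shears only when packed into Voigt vectors.

The finite-difference divergence used for the static-equilibrium
residual is second-order accurate everywhere: central differences at
interior voxels and one-sided three-point stencils on the boundary
layers, so the equilibrium loss is defined volume-wide without cropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .constitutive import VOIGT_ORDER

__all__ = [
    "VolumetricField",
    "strain_field",
    "stress_field",
    "orientation_field",
    "FaceCondition",
    "BoundaryTractions",
    "ScaleSet",
    "derivative_matrix",
    "apply_derivative",
    "equilibrium_residual",
    "extract_boundary_tractions",
    "nondimensionalize",
    "redimensionalize_params",
    "add_noise",
    "strain_to_voigt",
    "voigt_to_strain",
    "FACES",
]

#: the six block faces, named by axis and side
FACES = ("x-", "x+", "y-", "y+", "z-", "z+")

#: Voigt slot of the (axis_i, axis_j) stress component, symmetric
_COMP_INDEX = {
    (0, 0): 0, (1, 1): 1, (2, 2): 2,
    (0, 1): 3, (1, 0): 3,
    (1, 2): 4, (2, 1): 4,
    (0, 2): 5, (2, 0): 5,
}


@dataclass
class VolumetricField:
    """A C-channel field on a regular grid with physical voxel spacing."""

    values: np.ndarray                      # (C, nx, ny, nz)
    spacing: tuple[float, float, float]
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(f"expected (C, nx, ny, nz), got {self.values.shape}")
        if min(self.values.shape[1:]) < 3:
            raise ValueError("grid must be at least 3 voxels per axis")
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise ValueError(f"spacing must be three positive numbers: {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")
        if self.channel_names and len(self.channel_names) != self.values.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    def copy(self) -> "VolumetricField":
        return replace(self, values=self.values.copy())


def strain_field(values: np.ndarray, spacing) -> VolumetricField:
    """Wrap a (6, nx, ny, nz) array of tensor strain components."""
    values = np.asarray(values)
    if values.ndim != 4 or values.shape[0] != 6:
        raise ValueError(
            f"strain field needs exactly 6 channels, got shape {values.shape}")
    return VolumetricField(values, tuple(spacing), VOIGT_ORDER)


def stress_field(values: np.ndarray, spacing) -> VolumetricField:
    """Wrap a (6, nx, ny, nz) array of stress components."""
    return strain_field(values, spacing)


def orientation_field(values: np.ndarray, spacing) -> VolumetricField:
    """Wrap a (3, nx, ny, nz) array of Euler angles (psi, theta, phi)."""
    f = VolumetricField(values, tuple(spacing), ("psi", "theta", "phi"))
    if f.n_channels != 3:
        raise ValueError("orientation field needs exactly 3 channels")
    return f


# ---------------------------------------------------------------------------
# finite differences


@lru_cache(maxsize=64)
def derivative_matrix(n: int, h: float) -> sp.csr_matrix:
    """Sparse (n, n) first-derivative operator, second order everywhere.

    Central difference at interior points; three-point one-sided stencils
    (-3, 4, -1)/(2h) at the two boundary points.
    """
    if n < 3:
        raise ValueError("need at least 3 points for second-order stencils")
    D = sp.lil_matrix((n, n))
    inv2h = 1.0 / (2.0 * h)
    for i in range(1, n - 1):
        D[i, i - 1] = -inv2h
        D[i, i + 1] = inv2h
    D[0, 0], D[0, 1], D[0, 2] = -3.0 * inv2h, 4.0 * inv2h, -inv2h
    D[n - 1, n - 1], D[n - 1, n - 2], D[n - 1, n - 3] = (
        3.0 * inv2h, -4.0 * inv2h, inv2h,
    )
    return D.tocsr()


def apply_derivative(arr: np.ndarray, axis: int, h: float,
                     transpose: bool = False) -> np.ndarray:
    """d(arr)/d(axis) for a 3-D array; ``transpose=True`` applies the
    adjoint stencil (used for loss gradients)."""
    n = arr.shape[axis]
    D = derivative_matrix(n, float(h))
    if transpose:
        D = D.T
    moved = np.moveaxis(arr, axis, 0)
    out = (D @ moved.reshape(n, -1)).reshape(moved.shape)
    return np.moveaxis(out, 0, axis)


def equilibrium_residual(stress: VolumetricField) -> VolumetricField:
    """Divergence of the stress tensor, (3, nx, ny, nz).

    Zero for any field in static equilibrium without body forces; exact
    (to rounding) for constant and linear stress fields.
    """
    if stress.n_channels != 6:
        raise ValueError("stress field needs 6 channels")
    s = stress.values
    hx, hy, hz = stress.spacing
    res = np.empty((3,) + stress.grid_shape)
    for i in range(3):
        acc = np.zeros(stress.grid_shape)
        for j, h in zip(range(3), (hx, hy, hz)):
            acc += apply_derivative(s[_COMP_INDEX[i, j]], j, h)
        res[i] = acc
    return VolumetricField(res, stress.spacing, ("div_x", "div_y", "div_z"))


# ---------------------------------------------------------------------------
# boundaries


@dataclass(frozen=True)
class FaceCondition:
    """Prescribed traction state of one block face.

    kind "loaded": normal traction = ``normal_traction`` (negative in
    compression), tangential tractions zero; "frictionless": tangential
    tractions zero, normal traction unconstrained (roller support);
    "free": all three traction components zero.
    """

    kind: str
    normal_traction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("loaded", "frictionless", "free"):
            raise ValueError(f"unknown face condition {self.kind!r}")


@dataclass
class BoundaryTractions:
    """Per-face prescribed tractions for the six faces of the block."""

    faces: Mapping[str, FaceCondition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FACES) - set(self.faces)
        if missing:
            raise ValueError(f"missing face conditions: {sorted(missing)}")
        if not any(
            fc.kind == "loaded" and fc.normal_traction != 0.0
            for fc in self.faces.values()
        ):
            raise ValueError(
                "at least one face must carry a nonzero prescribed traction"
            )

    @classmethod
    def uniaxial(cls, axis: int, traction: float,
                 loaded_side: str = "+") -> "BoundaryTractions":
        """Loaded face on ``axis`` (0=x, 1=y, 2=z), frictionless opposite
        face, free lateral faces — the compression setup used throughout."""
        ax = "xyz"[axis]
        other = "-" if loaded_side == "+" else "+"
        faces = {f: FaceCondition("free") for f in FACES}
        faces[f"{ax}{loaded_side}"] = FaceCondition("loaded", traction)
        faces[f"{ax}{other}"] = FaceCondition("frictionless")
        return cls(faces)

    def max_traction(self) -> float:
        return max(
            abs(fc.normal_traction)
            for fc in self.faces.values() if fc.kind == "loaded"
        )

    def scaled(self, factor: float) -> "BoundaryTractions":
        return BoundaryTractions({
            name: (FaceCondition("loaded", fc.normal_traction * factor)
                   if fc.kind == "loaded" else fc)
            for name, fc in self.faces.items()
        })

    def loading_axis(self) -> int:
        for name, fc in self.faces.items():
            if fc.kind == "loaded" and fc.normal_traction != 0.0:
                return "xyz".index(name[0])
        raise ValueError("no loaded face")


def _face_slice(face: str, shape: tuple[int, int, int]):
    axis = "xyz".index(face[0])
    idx = [slice(None)] * 3
    idx[axis] = 0 if face[1] == "-" else shape[axis] - 1
    return axis, tuple(idx)


def extract_boundary_tractions(stress: VolumetricField) -> dict:
    """Measured per-face tractions of a stress field.

    For each face returns ``{"normal": 2-D map, "shear": (2, ...) maps}``
    where "normal" is n·sigma·n (so a compressive sigma_zz = -s0 reports
    -s0 on both z faces) and "shear" the two in-plane components of
    sigma·n in axis order.
    """
    out = {}
    for fname in FACES:
        axis, idx = _face_slice(fname, stress.grid_shape)
        others = [a for a in range(3) if a != axis]
        normal = stress.values[_COMP_INDEX[axis, axis]][idx]
        sign = 1.0 if fname[1] == "+" else -1.0
        shear = np.stack([
            sign * stress.values[_COMP_INDEX[axis, o]][idx] for o in others
        ])
        out[fname] = {"normal": normal, "shear": shear}
    return out


# ---------------------------------------------------------------------------
# scaling and noise


@dataclass(frozen=True)
class ScaleSet:
    """Stress and strain scales of a nondimensionalized problem.

    A dimensionless stiffness-like output P maps back to physical units
    as ``p = P * sigma_star / eps_star``.
    """

    sigma_star: float
    eps_star: float

    def __post_init__(self) -> None:
        if self.sigma_star <= 0 or self.eps_star <= 0:
            raise ValueError("scales must be positive")

    @property
    def stiffness_scale(self) -> float:
        return self.sigma_star / self.eps_star


def nondimensionalize(strain: VolumetricField, bc: BoundaryTractions):
    """Scale strains by their max magnitude and tractions by the largest
    prescribed traction; returns (scaled strain, scaled bc, ScaleSet)."""
    eps_star = float(np.abs(strain.values).max())
    if eps_star == 0.0:
        raise ValueError("zero strain field cannot be nondimensionalized")
    sigma_star = bc.max_traction()
    scaled = replace(strain, values=strain.values / eps_star)
    return scaled, bc.scaled(1.0 / sigma_star), ScaleSet(sigma_star, eps_star)


def redimensionalize_params(dimensionless: np.ndarray, scales: ScaleSet) -> np.ndarray:
    """Dimensionless stiffness-like parameters back to stress units."""
    return np.asarray(dimensionless) * scales.stiffness_scale


def add_noise(f: VolumetricField, fraction: float, seed: int) -> VolumetricField:
    """Add i.i.d. zero-mean Gaussian noise per channel with standard
    deviation ``fraction`` times that channel's standard deviation."""
    if fraction < 0:
        raise ValueError("noise fraction must be non-negative")
    if fraction == 0:
        return f.copy()
    rng = np.random.default_rng(seed)
    stds = f.values.reshape(f.n_channels, -1).std(axis=1)
    noise = rng.standard_normal(f.values.shape)
    noise *= (fraction * stds)[:, None, None, None]
    return replace(f, values=f.values + noise)


# ---------------------------------------------------------------------------
# Voigt packing

_SHEAR_DOUBLER = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


def strain_to_voigt(strain: VolumetricField, voxel_index=None) -> np.ndarray:
    """Pack tensor strain channels into engineering Voigt vectors.

    With ``voxel_index`` returns that voxel's 6-vector; otherwise the
    whole volume as an (N, 6) array in C (row-major) voxel order.
    """
    if voxel_index is not None:
        i, j, k = voxel_index
        return strain.values[:, i, j, k] * _SHEAR_DOUBLER
    flat = strain.values.reshape(6, -1).T
    return flat * _SHEAR_DOUBLER


def voigt_to_strain(voigt: np.ndarray, grid_shape, spacing) -> VolumetricField:
    """Inverse of :func:`strain_to_voigt` for full volumes."""
    vals = (np.asarray(voigt) / _SHEAR_DOUBLER).T.reshape((6,) + tuple(grid_shape))
    return strain_field(vals, spacing)
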