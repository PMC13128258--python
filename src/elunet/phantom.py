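"""Synthetic phantom generation for elasticity-imaging experiments.

Two families of ground-truth data stand in for an imaging + commercial
FEM pipeline:

* analytic phantoms (manufactured solutions and homogeneous blocks)
  whose strain fields satisfy equilibrium, compatibility and the
  constitutive law *exactly*, for discretization-free verification; and
* finite-element phantoms (stiff inclusions in a soft matrix, a layered
  fiber-reinforced cube) solved with the hexahedral solver in
  :mod:`elunet.fem`.

Default material values are the study conditions the phantoms emulate:
an isotropic brain-like set (white matter E=2 kPa/nu=0.35, gray matter
1.5/0.40, background 1/0.45) under compression reaching axial strains
of about -0.035, and a three-layer articular-cartilage set of
transversely isotropic constants (MPa) with per-layer fiber angles,
loaded by 0.05 N (0.0125 MPa) on each axis of a 2 mm cube in turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import constitutive as con
from .fem import solve_forward
from .fields import (
    BoundaryTractions,
    VolumetricField,
    add_noise,
    orientation_field,
    strain_field,
)

__all__ = [
    "PhantomDataset",
    "BRAIN_MATERIALS",
    "CARTILAGE_LAYERS",
    "manufactured_iso_phantom",
    "homogeneous_block_phantom",
    "fem_forward_solve",
    "inclusion_phantom",
    "cartilage_phantom",
]

#: isotropic brain-like example, (E [kPa], nu) per region
BRAIN_MATERIALS = {
    "white_matter": (2.0, 0.35),
    "gray_matter": (1.5, 0.40),
    "background": (1.0, 0.45),
}

#: articular-cartilage layers: (fiber angle [deg], Exx, Eyy, Gxy [MPa], nu_xy, nu_yz)
CARTILAGE_LAYERS = {
    "superficial": (35.0, 2.0, 0.4, 0.3, 0.35, 0.3),
    "intermediate": (60.0, 3.0, 0.6, 0.4, 0.4, 0.35),
    "deep": (80.0, 5.0, 1.0, 0.5, 0.45, 0.4),
}

#: compressive traction magnitude of the cartilage loadings: 0.05 N / (2 mm)^2
CARTILAGE_TRACTION = 0.0125  # MPa


@dataclass
class PhantomDataset:
    """Strains + boundary conditions + ground truth of one loading."""

    strain: VolumetricField
    bc: BoundaryTractions
    truth: dict[str, np.ndarray]
    labels: Optional[np.ndarray] = None
    orientation: Optional[VolumetricField] = None
    strain_noisy: Optional[VolumetricField] = None
    provenance: dict = field(default_factory=dict)

    @property
    def spacing(self):
        return self.strain.spacing


def _centers(n: int, h: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * h


# ---------------------------------------------------------------------------
# analytic phantoms


def manufactured_iso_phantom(n: int = 16, sigma0: float = 0.035,
                             e_range=(1.0, 2.0), nu_ends=(0.35, 0.44),
                             noise_fraction: float = 0.0,
                             seed: int = 0) -> PhantomDataset:
    """Exact heterogeneous uniaxial-stress phantom.

    Built from the displacement field ``u = (x g(z), y g(z),
    -(x^2+y^2) g'(z)/2 + h(z))`` with g linear, so the lateral strains
    ``exx = eyy = g(z)`` are linear in z, all shears vanish, and the only
    stress is the constant ``sigma_zz = -sigma0``: the stress field is
    exactly divergence-free and the strains exactly compatible at any
    grid size.  The modulus profile E(z) runs linearly across
    ``e_range`` (factor-2 contrast by default, in kPa) and the Poisson
    profile follows from ``nu(z) = exx(z) E(z) / sigma0`` with its end
    values set by ``nu_ends``.
    """
    h = 1.0 / n
    spacing = (h, h, h)
    z = _centers(n, h)                    # in (0, 1)
    E_lo, E_hi = e_range
    E_z = E_lo + (E_hi - E_lo) * z
    exx_ends = (nu_ends[0] * sigma0 / E_lo, nu_ends[1] * sigma0 / E_hi)
    exx_z = exx_ends[0] + (exx_ends[1] - exx_ends[0]) * z
    nu_z = exx_z * E_z / sigma0
    if np.any(nu_z <= 0.0) or np.any(nu_z >= 0.5):
        raise ValueError("requested profiles drive nu outside (0, 0.5)")
    ezz_z = -sigma0 / E_z

    vals = np.zeros((6, n, n, n))
    vals[0] = exx_z[None, None, :]
    vals[1] = exx_z[None, None, :]
    vals[2] = ezz_z[None, None, :]
    strain = strain_field(vals, spacing)
    bc = BoundaryTractions.uniaxial(2, -sigma0)

    shape = (n, n, n)
    E_vol = np.broadcast_to(E_z[None, None, :], shape).copy()
    nu_vol = np.broadcast_to(nu_z[None, None, :], shape).copy()
    lam = E_vol * nu_vol / ((1 + nu_vol) * (1 - 2 * nu_vol))
    mu = E_vol / (2 * (1 + nu_vol))
    truth = {"E": E_vol, "nu": nu_vol, "lam": lam, "mu": mu}
    noisy = add_noise(strain, noise_fraction, seed) if noise_fraction else None
    return PhantomDataset(
        strain, bc, truth, labels=np.zeros(shape, dtype=np.int32),
        strain_noisy=noisy,
        provenance={
            "kind": "manufactured_iso", "n": n, "sigma0": sigma0,
            "e_range": tuple(e_range), "nu_ends": tuple(nu_ends),
            "noise_fraction": noise_fraction, "seed": seed,
        },
    )


def homogeneous_block_phantom(n: int = 16, material=None, axis: int = 2,
                              sigma0: float = 0.035, fiber_angle_deg: float = 0.0,
                              spacing_total: float = 1.0,
                              noise_fraction: float = 0.0,
                              seed: int = 0) -> PhantomDataset:
    """Uniform-stress exact solution for a homogeneous block.

    ``material`` is either :class:`~elunet.constitutive.EngineeringIso`
    (default: the soft background, E=1 kPa, nu=0.45) or
    :class:`~elunet.constitutive.EngineeringTI` (with ``fiber_angle_deg``
    tilting the fiber axis about global Y).  Uniaxial compression of
    magnitude ``sigma0`` acts along ``axis``.
    """
    if material is None:
        material = con.EngineeringIso(*BRAIN_MATERIALS["background"])
    h = spacing_total / n
    spacing = (h, h, h)
    shape = (n, n, n)
    if isinstance(material, con.EngineeringIso):
        p = con.engineering_to_lame(material)
        C = con.assemble_isotropic_stiffness(p)
        orient = None
        truth = {
            "E": np.full(shape, material.E), "nu": np.full(shape, material.nu),
            "lam": np.full(shape, p.lam), "mu": np.full(shape, p.mu),
        }
    else:
        tloc = con.engineering_to_ti_local(material)
        theta = np.deg2rad(fiber_angle_deg)
        B = con.bond_matrix(con.rotation_for_fiber_angle(theta))
        C = con.rotate_stiffness(con.assemble_ti_local_stiffness(tloc), B)
        ov = np.zeros((3,) + shape)
        ov[1] = theta
        orient = orientation_field(ov, spacing)
        truth = {
            "Exx": np.full(shape, material.Exx),
            "Eyy": np.full(shape, material.Eyy),
            "nu_xy": np.full(shape, material.nu_xy),
            "nu_yz": np.full(shape, material.nu_yz),
            "Gxy": np.full(shape, material.Gxy),
        }
    sig = np.zeros(6)
    sig[axis] = -sigma0
    eps = np.linalg.solve(C, sig)          # engineering shears
    eps[3:] *= 0.5
    vals = np.broadcast_to(eps[:, None, None, None], (6,) + shape).copy()
    strain = strain_field(vals, spacing)
    bc = BoundaryTractions.uniaxial(axis, -sigma0)
    noisy = add_noise(strain, noise_fraction, seed) if noise_fraction else None
    return PhantomDataset(
        strain, bc, truth, labels=np.zeros(shape, dtype=np.int32),
        orientation=orient, strain_noisy=noisy,
        provenance={
            "kind": "homogeneous_block", "n": n, "axis": axis,
            "sigma0": sigma0, "fiber_angle_deg": fiber_angle_deg,
            "material": repr(material), "noise_fraction": noise_fraction,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# finite-element phantoms


def fem_forward_solve(stiffness: np.ndarray, spacing, bc: BoundaryTractions,
                      truth: dict, labels=None, orientation=None,
                      noise_fraction: float = 0.0, seed: int = 0,
                      provenance=None) -> PhantomDataset:
    """Forward-solve a per-voxel stiffness volume and package the result."""
    res = solve_forward(np.asarray(stiffness), spacing, bc)
    strain = res.strain
    noisy = add_noise(strain, noise_fraction, seed) if noise_fraction else None
    prov = dict(provenance or {})
    prov.update({"force_balance_error": res.reaction_imbalance,
                 "noise_fraction": noise_fraction, "seed": seed})
    return PhantomDataset(strain, bc, truth, labels=labels,
                          orientation=orientation, strain_noisy=noisy,
                          provenance=prov)


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) + 0.5 for n in shape], indexing="ij")
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def inclusion_phantom(n: int = 16, sigma0: float = 0.035,
                      materials=None, noise_fraction: float = 0.0,
                      seed: int = 0) -> PhantomDataset:
    """Two stiff inclusions in a soft background under z compression.

    Region moduli follow the brain-like set: background (label 0)
    E=1 kPa/nu=0.45, a stiff ellipsoid (label 1) E=2/0.35 and a medium
    ellipsoid (label 2) E=1.5/0.40.  Geometry (centers, radii) is drawn
    reproducibly from ``seed``.
    """
    if materials is None:
        materials = [
            con.EngineeringIso(*BRAIN_MATERIALS["background"]),
            con.EngineeringIso(*BRAIN_MATERIALS["white_matter"]),
            con.EngineeringIso(*BRAIN_MATERIALS["gray_matter"]),
        ]
    rng = np.random.default_rng(seed)
    shape = (n, n, n)
    labels = np.zeros(shape, dtype=np.int32)
    # stiff inclusion in the lower half, medium one in the upper half
    for label, zone in ((1, (0.25, 0.45)), (2, (0.55, 0.75))):
        center = np.array([rng.uniform(0.35, 0.65) * n,
                           rng.uniform(0.35, 0.65) * n,
                           rng.uniform(*zone) * n])
        radii = rng.uniform(0.12, 0.2, size=3) * n
        labels[_ellipsoid_mask(shape, center, radii)] = label
    h = 1.0 / n
    C = np.empty(shape + (6, 6))
    truth = {k: np.empty(shape) for k in ("E", "nu", "lam", "mu")}
    for label, mat in enumerate(materials):
        p = con.engineering_to_lame(mat)
        mask = labels == label
        C[mask] = con.assemble_isotropic_stiffness(p)
        truth["E"][mask], truth["nu"][mask] = mat.E, mat.nu
        truth["lam"][mask], truth["mu"][mask] = p.lam, p.mu
    bc = BoundaryTractions.uniaxial(2, -sigma0)
    return fem_forward_solve(
        C, (h, h, h), bc, truth, labels=labels,
        noise_fraction=noise_fraction, seed=seed,
        provenance={"kind": "inclusion", "n": n, "sigma0": sigma0,
                    "materials": [repr(m) for m in materials]},
    )


def cartilage_phantom(n: int = 24, traction: float = CARTILAGE_TRACTION,
                      layers=None, size_mm: float = 2.0,
                      noise_fraction: float = 0.0, seed: int = 0):
    """Three-layer transversely isotropic cube under X, Y and Z
    compression (one forward solve per axis).

    Layers stack along z — deep at the bottom, intermediate, superficial
    at the top, each one third of the height — with per-layer fiber
    angles and engineering constants (MPa).  Returns ``(datasets,
    orientation)`` where the three datasets share truth, labels and
    orientation volumes.
    """
    if layers is None:
        layers = CARTILAGE_LAYERS
    names = ("deep", "intermediate", "superficial")     # bottom to top
    h = size_mm / n
    shape = (n, n, n)
    labels = np.zeros(shape, dtype=np.int32)
    bounds = np.linspace(0, n, 4).astype(int)
    C = np.empty(shape + (6, 6))
    ov = np.zeros((3,) + shape)
    keys = ("Exx", "Eyy", "nu_xy", "nu_yz", "Gxy")
    truth = {k: np.empty(shape) for k in keys}
    for li, name in enumerate(names):
        angle_deg, Exx, Eyy, Gxy, nxy, nyz = layers[name]
        mat = con.EngineeringTI(Exx=Exx, Eyy=Eyy, nu_xy=nxy, nu_yz=nyz, Gxy=Gxy)
        tloc = con.engineering_to_ti_local(mat)
        theta = np.deg2rad(angle_deg)
        B = con.bond_matrix(con.rotation_for_fiber_angle(theta))
        Cg = con.rotate_stiffness(con.assemble_ti_local_stiffness(tloc), B)
        zsl = slice(bounds[li], bounds[li + 1])
        labels[:, :, zsl] = li
        C[:, :, zsl] = Cg
        ov[1, :, :, zsl] = theta
        for k, v in zip(keys, (Exx, Eyy, nxy, nyz, Gxy)):
            truth[k][:, :, zsl] = v
    orientation = orientation_field(ov, (h, h, h))
    datasets = []
    for axis in range(3):
        bc = BoundaryTractions.uniaxial(axis, -traction)
        ds = fem_forward_solve(
            C, (h, h, h), bc, truth, labels=labels, orientation=orientation,
            noise_fraction=noise_fraction, seed=seed + axis,
            provenance={"kind": "cartilage", "n": n, "axis": axis,
                        "traction": traction, "size_mm": size_mm,
                        "fiber_angle_interpretation":
                            "theta about global Y; psi=phi=0"},
        )
        datasets.append(ds)
    return datasets, orientation
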