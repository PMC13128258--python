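"""Pointwise linear-elasticity algebra in Voigt notation.

Everything here operates on 6x6 stiffness matrices in the Voigt order
``(xx, yy, zz, xy, yz, xz)`` acting on engineering-shear strain vectors
``(exx, eyy, ezz, 2exy, 2eyz, 2exz)``.  Two material symmetries are
supported: isotropy (Lame parameters lam, mu) and transverse isotropy
(five independent local stiffness terms c11, c12, c22, c23, c44, with
x' the longitudinal/fiber axis and y'z' the isotropic transverse plane).

Frame changes go through the Bond transformation: a rotation built from
Z-Y'-Z'' Euler angles gives the direction-cosine matrix T (global ->
local), the 6x6 Bond matrix B maps engineering strain vectors from the
global to the local frame, and the lab-frame stiffness follows as
C = B^T C' B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IsotropicParams",
    "EngineeringIso",
    "TILocalStiffness",
    "EngineeringTI",
    "EulerAngles",
    "VOIGT_ORDER",
    "assemble_isotropic_stiffness",
    "lame_to_engineering",
    "engineering_to_lame",
    "assemble_ti_local_stiffness",
    "engineering_to_ti_local",
    "ti_local_to_engineering",
    "euler_rotation",
    "transformation_matrix",
    "bond_matrix",
    "rotate_stiffness",
    "ti_stiffness_basis",
    "euler_rotation_batch",
    "bond_matrix_batch",
    "lame_to_engineering_arrays",
    "ti_local_to_engineering_arrays",
    "rotation_for_fiber_angle",
    "AdmissibilityError",
]

#: Voigt component order used throughout the package.
VOIGT_ORDER = ("xx", "yy", "zz", "xy", "yz", "xz")

#: (i, j) tensor index pairs for each Voigt slot.
VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2))


class AdmissibilityError(ValueError):
    """Raised for material parameters outside the thermodynamically stable set."""


@dataclass(frozen=True)
class IsotropicParams:
    """First and second Lame parameters (stress units, or dimensionless)."""

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.mu > 0.0):
            raise AdmissibilityError(f"mu must be positive, got {self.mu}")
        if not (3.0 * self.lam + 2.0 * self.mu > 0.0):
            raise AdmissibilityError(
                f"3*lam + 2*mu must be positive, got lam={self.lam}, mu={self.mu}"
            )


@dataclass(frozen=True)
class EngineeringIso:
    """Elastic modulus and Poisson's ratio of an isotropic solid."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.E > 0.0):
            raise AdmissibilityError(f"E must be positive, got {self.E}")
        if not (-1.0 < self.nu < 0.5):
            raise AdmissibilityError(f"nu must lie in (-1, 0.5), got {self.nu}")


@dataclass(frozen=True)
class TILocalStiffness:
    """Five independent stiffness terms of a transversely isotropic solid.

    Defined in the material (fiber-aligned) frame: x' longitudinal,
    y'z' the isotropy plane.
    """

    c11: float
    c12: float
    c22: float
    c23: float
    c44: float

    def __post_init__(self) -> None:
        C = _ti_matrix(self.c11, self.c12, self.c22, self.c23, self.c44)
        # symmetric by construction; positive definiteness is the real constraint
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise AdmissibilityError(
                "local TI stiffness matrix is not positive definite: "
                f"{self}"
            ) from exc


@dataclass(frozen=True)
class EngineeringTI:
    """Engineering constants of a transversely isotropic solid.

    ``Exx`` is the longitudinal (fiber-direction) modulus, ``Eyy`` the
    transverse modulus, ``nu_xy`` the longitudinal-transverse Poisson's
    ratio, ``nu_yz`` the transverse-plane Poisson's ratio and ``Gxy``
    the longitudinal shear modulus.  The transverse-plane shear modulus
    ``Gyz = Eyy / (2 (1 + nu_yz))`` is not independent.
    """

    Exx: float
    Eyy: float
    nu_xy: float
    nu_yz: float
    Gxy: float

    def __post_init__(self) -> None:
        if min(self.Exx, self.Eyy, self.Gxy) <= 0.0:
            raise AdmissibilityError(f"moduli must be positive: {self}")
        S = _ti_compliance(self)
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise AdmissibilityError(
                f"TI compliance is not positive definite: {self}"
            ) from exc

    @property
    def Gyz(self) -> float:
        return self.Eyy / (2.0 * (1.0 + self.nu_yz))


@dataclass(frozen=True)
class EulerAngles:
    """Z-Y'-Z'' Euler angles (radians): psi about Z, theta about the
    rotated Y', phi about Z''."""

    psi: float
    theta: float
    phi: float


# ---------------------------------------------------------------------------
# isotropic stiffness and conversions


def assemble_isotropic_stiffness(p: IsotropicParams) -> np.ndarray:
    """6x6 isotropic stiffness: normal diagonal 2*mu+lam, normal
    off-diagonal lam, shear diagonal mu."""
    lam, mu = p.lam, p.mu
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = 2.0 * mu + lam
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def lame_to_engineering_arrays(lam, mu):
    """Elementwise (lam, mu) -> (E, nu) for arrays of any shape."""
    lam, mu = np.asarray(lam), np.asarray(mu)
    denom = lam + mu
    if np.any(denom == 0.0):
        raise AdmissibilityError("lam + mu = 0: singular parameter combination")
    return mu * (3.0 * lam + 2.0 * mu) / denom, lam / (2.0 * denom)


def lame_to_engineering(p: IsotropicParams) -> EngineeringIso:
    """(lam, mu) -> (E, nu): E = mu(3 lam + 2 mu)/(lam + mu),
    nu = lam / (2 (lam + mu))."""
    E, nu = lame_to_engineering_arrays(p.lam, p.mu)
    return EngineeringIso(E=float(E), nu=float(nu))


def engineering_to_lame(e: EngineeringIso) -> IsotropicParams:
    """(E, nu) -> (lam, mu); closed-form inverse of :func:`lame_to_engineering`."""
    if e.nu >= 0.5:
        raise AdmissibilityError("nu = 0.5 is the incompressible limit")
    mu = e.E / (2.0 * (1.0 + e.nu))
    lam = e.E * e.nu / ((1.0 + e.nu) * (1.0 - 2.0 * e.nu))
    return IsotropicParams(lam=lam, mu=mu)


# ---------------------------------------------------------------------------
# transversely isotropic stiffness and conversions


def _ti_matrix(c11, c12, c22, c23, c44) -> np.ndarray:
    C = np.array(
        [
            [c11, c12, c12, 0.0, 0.0, 0.0],
            [c12, c22, c23, 0.0, 0.0, 0.0],
            [c12, c23, c22, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, c44, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.5 * (c22 - c23), 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, c44],
        ]
    )
    return C


def assemble_ti_local_stiffness(t: TILocalStiffness) -> np.ndarray:
    """6x6 local TI stiffness.

    The transverse-shear (yz, yz) entry is ``(c22 - c23)/2`` so that the
    y'z' plane is exactly the isotropy plane.
    """
    return _ti_matrix(t.c11, t.c12, t.c22, t.c23, t.c44)


def ti_stiffness_basis() -> np.ndarray:
    """(5, 6, 6) basis: stack of dC'/dc_k for k in (c11, c12, c22, c23, c44).

    The local TI stiffness is linear in its five parameters,
    ``C'(c) = sum_k c_k * basis[k]``; downstream losses exploit this.
    """
    zeros = np.zeros(5)
    basis = np.empty((5, 6, 6))
    for k in range(5):
        c = zeros.copy()
        c[k] = 1.0
        basis[k] = _ti_matrix(*c)
    return basis


def _ti_compliance(e: EngineeringTI) -> np.ndarray:
    """Local TI compliance from engineering constants (x' longitudinal)."""
    Ex, Ey, nxy, nyz, Gxy = e.Exx, e.Eyy, e.nu_xy, e.nu_yz, e.Gxy
    Gyz = Ey / (2.0 * (1.0 + nyz))
    S = np.zeros((6, 6))
    S[0, 0] = 1.0 / Ex
    S[1, 1] = S[2, 2] = 1.0 / Ey
    S[0, 1] = S[1, 0] = S[0, 2] = S[2, 0] = -nxy / Ex
    S[1, 2] = S[2, 1] = -nyz / Ey
    S[3, 3] = S[5, 5] = 1.0 / Gxy
    S[4, 4] = 1.0 / Gyz
    return S


def engineering_to_ti_local(e: EngineeringTI) -> TILocalStiffness:
    """Engineering constants -> five local stiffness terms (compliance
    inversion)."""
    S = _ti_compliance(e)
    C = np.linalg.inv(S)
    return TILocalStiffness(
        c11=C[0, 0], c12=C[0, 1], c22=C[1, 1], c23=C[1, 2], c44=C[3, 3]
    )


def ti_local_to_engineering(t: TILocalStiffness) -> EngineeringTI:
    """Five local stiffness terms -> engineering constants.

    Exx = (-2 c12^2 + c11 c22 + c11 c23) / (c22 + c23)
    Eyy = (c22 - c23)(-2 c12^2 + c11 c22 + c11 c23) / (c11 c22 - c12^2)
    nu_xy = c12 / (c22 + c23)
    nu_yz = (c11 c23 - c12^2) / (c11 c22 - c12^2)
    Gxy = c44                    (and Gyz = (c22 - c23)/2, dependent)
    """
    out = ti_local_to_engineering_arrays(t.c11, t.c12, t.c22, t.c23, t.c44)
    return EngineeringTI(*(float(v) for v in out[:5]))


def ti_local_to_engineering_arrays(c11, c12, c22, c23, c44):
    """Elementwise stiffness-to-engineering conversion for arrays.

    Returns (Exx, Eyy, nu_xy, nu_yz, Gxy, Gyz)."""
    c11, c12, c22, c23, c44 = (np.asarray(a) for a in (c11, c12, c22, c23, c44))
    d1 = c22 + c23
    d2 = c11 * c22 - c12 * c12
    if np.any(d1 == 0.0) or np.any(d2 == 0.0):
        raise AdmissibilityError("singular stiffness-to-engineering conversion")
    num = -2.0 * c12 * c12 + c11 * c22 + c11 * c23
    return (num / d1, (c22 - c23) * num / d2, c12 / d1,
            (c11 * c23 - c12 * c12) / d2, c44, (c22 - c23) / 2.0)


# ---------------------------------------------------------------------------
# rotations


def euler_rotation(a: EulerAngles) -> np.ndarray:
    """Rotation matrix R = Z(psi) @ Y'(theta) @ Z''(phi).

    Each factor maps global vector components to the rotated frame, so R
    itself maps global components to local (fiber-frame) components.
    """
    cps, sps = np.cos(a.psi), np.sin(a.psi)
    cth, sth = np.cos(a.theta), np.sin(a.theta)
    cph, sph = np.cos(a.phi), np.sin(a.phi)
    Z = np.array([[cps, sps, 0.0], [-sps, cps, 0.0], [0.0, 0.0, 1.0]])
    Y = np.array([[cth, 0.0, sth], [0.0, 1.0, 0.0], [-sth, 0.0, cth]])
    Z2 = np.array([[cph, sph, 0.0], [-sph, cph, 0.0], [0.0, 0.0, 1.0]])
    return Z @ Y @ Z2


def transformation_matrix(R: np.ndarray) -> np.ndarray:
    """Direction-cosine matrix T with t_ij = cos(local axis i', global axis j).

    For the Z-Y'-Z'' construction (u' = R u) this is R itself; kept as a
    named step so the convention is explicit at call sites.
    """
    return np.asarray(R)


def bond_matrix(T: np.ndarray) -> np.ndarray:
    """6x6 Bond matrix B for the Voigt order (xx, yy, zz, xy, yz, xz).

    B maps global engineering-strain vectors to the local frame,
    eps'_voigt = B eps_voigt; the factor-2 entries sit in the lower-left
    3x3 block.  For stiffness, C_global = B^T C'_local B.
    """
    return bond_matrix_batch(np.asarray(T, dtype=float))


def rotate_stiffness(C_local: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Lab-frame stiffness C = B^T C' B."""
    C_local = np.asarray(C_local)
    return B.T @ C_local @ B


def euler_rotation_batch(psi: np.ndarray, theta: np.ndarray,
                         phi: np.ndarray) -> np.ndarray:
    """Vectorized :func:`euler_rotation`: three (N,) angle arrays ->
    (N, 3, 3) rotation matrices."""
    psi, theta, phi = (np.asarray(a, dtype=float).ravel() for a in (psi, theta, phi))
    n = psi.size
    cps, sps = np.cos(psi), np.sin(psi)
    cth, sth = np.cos(theta), np.sin(theta)
    cph, sph = np.cos(phi), np.sin(phi)
    Z = np.zeros((n, 3, 3))
    Z[:, 0, 0], Z[:, 0, 1], Z[:, 1, 0], Z[:, 1, 1], Z[:, 2, 2] = cps, sps, -sps, cps, 1.0
    Y = np.zeros((n, 3, 3))
    Y[:, 0, 0], Y[:, 0, 2], Y[:, 1, 1], Y[:, 2, 0], Y[:, 2, 2] = cth, sth, 1.0, -sth, cth
    Z2 = np.zeros((n, 3, 3))
    Z2[:, 0, 0], Z2[:, 0, 1], Z2[:, 1, 0], Z2[:, 1, 1], Z2[:, 2, 2] = cph, sph, -sph, cph, 1.0
    return Z @ Y @ Z2


_BOND_ROWS = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0))


def bond_matrix_batch(T: np.ndarray) -> np.ndarray:
    """Vectorized :func:`bond_matrix`: (N, 3, 3) -> (N, 6, 6)."""
    T = np.asarray(T, dtype=float)
    B = np.empty(T.shape[:-2] + (6, 6))
    for a, (i, j) in enumerate(_BOND_ROWS):
        for b, (p, q) in enumerate(_BOND_ROWS):
            if a < 3:
                B[..., a, b] = T[..., i, p] * T[..., i, q]
            elif b < 3:
                B[..., a, b] = 2.0 * T[..., i, p] * T[..., j, p]
            else:
                B[..., a, b] = (T[..., i, p] * T[..., j, q]
                                + T[..., i, q] * T[..., j, p])
    return B


def rotation_for_fiber_angle(theta: float) -> np.ndarray:
    """Rotation tilting the longitudinal axis x' by ``theta`` (radians)
    about the global Y axis; the single-angle convention used for layered
    fiber phantoms (psi = phi = 0)."""
    return euler_rotation(EulerAngles(psi=0.0, theta=theta, phi=0.0))
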