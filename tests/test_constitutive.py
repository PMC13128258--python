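"""Pointwise elasticity algebra: assemblies, conversions, rotations.

The Bond-transformation tests compare against an independent brute-force
oracle that rotates the full 4th-order stiffness tensor index by index.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elunet.constitutive import (
    AdmissibilityError,
    EngineeringIso,
    EngineeringTI,
    EulerAngles,
    IsotropicParams,
    VOIGT_PAIRS,
    assemble_isotropic_stiffness,
    assemble_ti_local_stiffness,
    bond_matrix,
    bond_matrix_batch,
    engineering_to_lame,
    engineering_to_ti_local,
    euler_rotation,
    euler_rotation_batch,
    lame_to_engineering,
    rotate_stiffness,
    rotation_for_fiber_angle,
    ti_local_to_engineering,
    transformation_matrix,
)
from conftest import random_admissible_iso, random_admissible_ti

# Brain-like isotropic set (E [kPa], nu) and cartilage TI rows
# (angle deg, Exx, Eyy, Gxy, nu_xy, nu_yz in MPa) used as reference inputs.
WHITE_MATTER = (2.0, 0.35)
BACKGROUND = (1.0, 0.45)
SUPERFICIAL = dict(Exx=2.0, Eyy=0.4, nu_xy=0.35, nu_yz=0.3, Gxy=0.3)
DEEP = dict(Exx=5.0, Eyy=1.0, nu_xy=0.45, nu_yz=0.4, Gxy=0.5)


# -- independent oracle: brute-force 4th-order tensor rotation --------------


def voigt_to_tensor(C):
    Ct = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(VOIGT_PAIRS):
        for b, (k, l) in enumerate(VOIGT_PAIRS):
            Ct[i, j, k, l] = Ct[j, i, k, l] = Ct[i, j, l, k] = Ct[j, i, l, k] = C[a, b]
    return Ct


def tensor_to_voigt(Ct):
    C = np.zeros((6, 6))
    for a, (i, j) in enumerate(VOIGT_PAIRS):
        for b, (k, l) in enumerate(VOIGT_PAIRS):
            C[a, b] = Ct[i, j, k, l]
    return C


def rotate_tensor_oracle(C_local, T):
    """Local -> global stiffness by rotating C'_pqrs with Q = T^T."""
    Q = np.asarray(T).T
    Ct = voigt_to_tensor(C_local)
    return tensor_to_voigt(np.einsum("ip,jq,kr,ls,pqrs->ijkl", Q, Q, Q, Q, Ct))


# -- isotropic assembly and conversions -------------------------------------


class TestIsotropic:
    @pytest.mark.parametrize(
        "lam,mu,normal_diag,off,shear",
        [(0.0, 1.0, 2.0, 0.0, 1.0), (1.0, 1.0, 3.0, 1.0, 1.0)],
    )
    def test_assembly_pattern(self, lam, mu, normal_diag, off, shear):
        C = assemble_isotropic_stiffness(IsotropicParams(lam, mu))
        assert np.allclose(np.diag(C), [normal_diag] * 3 + [shear] * 3)
        assert C[0, 1] == C[1, 2] == off
        assert np.array_equal(C, C.T)
        assert np.abs(C[:3, 3:]).max() == 0.0

    def test_uniaxial_stress_state(self):
        # (E=2, nu=0.35): uniaxial compliance solution recovered by C @ eps
        E, nu = WHITE_MATTER
        p = engineering_to_lame(EngineeringIso(E, nu))
        C = assemble_isotropic_stiffness(p)
        s0 = 1.7
        eps = np.array([nu * s0 / E, nu * s0 / E, -s0 / E, 0, 0, 0])
        sig = C @ eps
        assert np.allclose(sig, [0, 0, -s0, 0, 0, 0], atol=1e-12)

    @pytest.mark.parametrize(
        "lam,mu,E,nu", [(1.0, 1.0, 2.5, 0.25), (0.0, 1.0, 2.0, 0.0)]
    )
    def test_lame_to_engineering_closed_form(self, lam, mu, E, nu):
        e = lame_to_engineering(IsotropicParams(lam, mu))
        assert e.E == pytest.approx(E) and e.nu == pytest.approx(nu)

    @pytest.mark.parametrize("E,nu", [WHITE_MATTER, BACKGROUND, (1.5, 0.4)])
    def test_round_trip_table_values(self, E, nu):
        back = lame_to_engineering(engineering_to_lame(EngineeringIso(E, nu)))
        assert back.E == pytest.approx(E, rel=1e-12)
        assert back.nu == pytest.approx(nu, rel=1e-12, abs=1e-12)

    def test_round_trip_random(self, rng):
        for _ in range(1000):
            E, nu = random_admissible_iso(rng)
            back = lame_to_engineering(engineering_to_lame(EngineeringIso(E, nu)))
            assert back.E == pytest.approx(E, rel=1e-10)
            assert back.nu == pytest.approx(nu, rel=1e-10, abs=1e-10)

    def test_rejects_inadmissible(self):
        with pytest.raises(AdmissibilityError):
            IsotropicParams(lam=1.0, mu=-0.1)
        with pytest.raises(AdmissibilityError):
            EngineeringIso(E=1.0, nu=0.5)
        with pytest.raises(AdmissibilityError):
            EngineeringIso(E=-2.0, nu=0.3)


# -- transversely isotropic --------------------------------------------------


class TestTransverselyIsotropic:
    def test_isotropic_degenerate_assembly(self):
        lam, mu = 1.3, 0.7
        t = engineering_to_ti_local(EngineeringTI(
            Exx=2 * mu * (1.5 * lam + mu) / (lam + mu),
            Eyy=2 * mu * (1.5 * lam + mu) / (lam + mu),
            nu_xy=lam / (2 * (lam + mu)), nu_yz=lam / (2 * (lam + mu)),
            Gxy=mu))
        C = assemble_ti_local_stiffness(t)
        C_iso = assemble_isotropic_stiffness(IsotropicParams(lam, mu))
        assert np.allclose(C, C_iso, atol=1e-10)

    @pytest.mark.parametrize("row", [SUPERFICIAL, DEEP,
                                     dict(Exx=3.0, Eyy=0.6, nu_xy=0.4,
                                          nu_yz=0.35, Gxy=0.4)])
    def test_round_trip_cartilage_rows(self, row):
        mat = EngineeringTI(**row)
        back = ti_local_to_engineering(engineering_to_ti_local(mat))
        for k, v in row.items():
            assert getattr(back, k) == pytest.approx(v, rel=1e-10)

    def test_assembled_matrix_positive_definite_and_symmetric(self):
        t = engineering_to_ti_local(EngineeringTI(**SUPERFICIAL))
        C = assemble_ti_local_stiffness(t)
        assert np.abs(C - C.T).max() == 0.0
        assert np.linalg.eigvalsh(C).min() > 0

    def test_transverse_shear_is_isotropy_plane(self):
        # the (yz, yz) entry must couple the transverse constants, making
        # y'z' the isotropy plane: Gyz = Eyy / (2 (1 + nu_yz))
        mat = EngineeringTI(**DEEP)
        t = engineering_to_ti_local(mat)
        C = assemble_ti_local_stiffness(t)
        assert C[4, 4] == pytest.approx((t.c22 - t.c23) / 2, rel=1e-12)
        assert C[4, 4] == pytest.approx(mat.Gyz, rel=1e-10)

    def test_round_trip_random(self, rng):
        for _ in range(1000):
            mat = random_admissible_ti(rng)
            back = ti_local_to_engineering(engineering_to_ti_local(mat))
            for k in ("Exx", "Eyy", "nu_xy", "nu_yz", "Gxy"):
                assert getattr(back, k) == pytest.approx(
                    getattr(mat, k), rel=1e-10)


# -- rotations and the Bond transformation -----------------------------------


class TestRotations:
    def test_identity_angles(self):
        assert np.allclose(euler_rotation(EulerAngles(0, 0, 0)), np.eye(3))

    def test_single_axis_psi(self):
        R = euler_rotation(EulerAngles(np.pi / 2, 0, 0))
        assert np.allclose(R, [[0, 1, 0], [-1, 0, 0], [0, 0, 1]], atol=1e-15)

    @given(st.tuples(st.floats(-np.pi, np.pi), st.floats(-np.pi, np.pi),
                     st.floats(-np.pi, np.pi)))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_orthogonality(self, angles):
        R = euler_rotation(EulerAngles(*angles))
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_transformation_matrix_psi_cosine(self):
        psi = 0.7
        T = transformation_matrix(euler_rotation(EulerAngles(psi, 0, 0)))
        assert T[0, 0] == pytest.approx(np.cos(psi))
        assert np.allclose(np.linalg.norm(T, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(T, axis=1), 1.0)

    def test_fiber_angle_tilts_longitudinal_axis(self):
        theta = np.deg2rad(35.0)
        T = rotation_for_fiber_angle(theta)
        x_local_in_global = T.T[:, 0]
        assert x_local_in_global == pytest.approx(
            [np.cos(theta), 0.0, np.sin(theta)])


class TestBond:
    def test_identity(self):
        assert np.allclose(bond_matrix(np.eye(3)), np.eye(6))

    def test_isotropy_invariance(self, rng):
        C = assemble_isotropic_stiffness(IsotropicParams(1.7, 0.74))
        for _ in range(20):
            B = bond_matrix(euler_rotation(EulerAngles(*rng.uniform(-np.pi, np.pi, 3))))
            assert np.abs(rotate_stiffness(C, B) - C).max() < 1e-10

    def test_oracle_equivalence_100_random(self, rng):
        for _ in range(100):
            angles = rng.uniform(-np.pi, np.pi, 3)
            T = transformation_matrix(euler_rotation(EulerAngles(*angles)))
            mat = random_admissible_ti(rng)
            Cl = assemble_ti_local_stiffness(engineering_to_ti_local(mat))
            got = rotate_stiffness(Cl, bond_matrix(T))
            want = rotate_tensor_oracle(Cl, T)
            assert np.abs(got - want).max() < 1e-9

    def test_eigenvalues_preserved(self, rng):
        mat = random_admissible_ti(rng)
        Cl = assemble_ti_local_stiffness(engineering_to_ti_local(mat))
        B = bond_matrix(euler_rotation(EulerAngles(0.3, -1.1, 2.0)))
        got = np.linalg.eigvalsh(rotate_stiffness(Cl, B))
        want = np.linalg.eigvalsh(rotate_tensor_oracle(
            Cl, euler_rotation(EulerAngles(0.3, -1.1, 2.0))))
        assert np.allclose(got, want, rtol=1e-9)

    def test_inverse_rotation_round_trip(self, rng):
        mat = random_admissible_ti(rng)
        Cl = assemble_ti_local_stiffness(engineering_to_ti_local(mat))
        a = EulerAngles(0.4, 0.9, -0.6)
        B = bond_matrix(euler_rotation(a))
        C_glob = rotate_stiffness(Cl, B)
        # inverse: rotate back with B^-1 = Bond(T^T)
        Binv = bond_matrix(euler_rotation(a).T)
        assert np.abs(rotate_stiffness(C_glob, Binv) - Cl).max() < 1e-10

    def test_symmetry_and_definiteness_preserved(self, rng):
        for _ in range(20):
            mat = random_admissible_ti(rng)
            Cl = assemble_ti_local_stiffness(engineering_to_ti_local(mat))
            B = bond_matrix(euler_rotation(
                EulerAngles(*rng.uniform(-np.pi, np.pi, 3))))
            C = rotate_stiffness(Cl, B)
            assert np.abs(C - C.T).max() < 1e-12
            assert np.linalg.eigvalsh(C).min() > 0

    def test_batch_matches_scalar(self, rng):
        angles = rng.uniform(-np.pi, np.pi, (10, 3))
        Rb = euler_rotation_batch(angles[:, 0], angles[:, 1], angles[:, 2])
        Bb = bond_matrix_batch(Rb)
        for i in range(10):
            R = euler_rotation(EulerAngles(*angles[i]))
            assert np.allclose(Rb[i], R, atol=1e-14)
            assert np.allclose(Bb[i], bond_matrix(R), atol=1e-14)
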