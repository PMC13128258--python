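"""Physics losses: zero on consistent fields, exact gradients, oracles."""

import numpy as np
import pytest

from elunet.constitutive import (
    EulerAngles,
    IsotropicParams,
    assemble_isotropic_stiffness,
    bond_matrix,
    euler_rotation,
    ti_stiffness_basis,
)
from elunet.fields import (
    BoundaryTractions,
    orientation_field,
    strain_field,
    strain_to_voigt,
)
from elunet.losses import (
    AdaptiveWeights,
    ConstitutiveIso,
    ConstitutiveTI,
    BoundaryLoss,
    TotalLossIso,
    TotalLossTI,
    equilibrium_loss,
    update_adaptive_weights,
)

GRID = (5, 4, 6)
SPACING = (0.1, 0.12, 0.09)
N = int(np.prod(GRID))


@pytest.fixture()
def strain(rng):
    return strain_field(rng.standard_normal((6,) + GRID) * 0.01, SPACING)


@pytest.fixture()
def weights():
    return AdaptiveWeights(GRID)


class TestConstitutiveIso:
    def test_exact_stress_zero_residual(self, strain, weights):
        lam0, mu0 = 1.3, 0.7
        sig = strain_to_voigt(strain) @ assemble_isotropic_stiffness(
            IsotropicParams(lam0, mu0)).T
        op = ConstitutiveIso(strain)
        loss, *_ = op.loss_and_grads(np.full(N, lam0), np.full(N, mu0), sig,
                                     weights)
        assert loss < 1e-28
        assert np.abs(weights.g_const).max() < 1e-25

    def test_residual_monotone_in_parameter_error(self, strain, weights):
        lam0, mu0 = 1.3, 0.7
        sig = strain_to_voigt(strain) @ assemble_isotropic_stiffness(
            IsotropicParams(lam0, mu0)).T
        op = ConstitutiveIso(strain)
        losses = [
            op.loss_and_grads(np.full(N, lam0), np.full(N, mu0 + d), sig,
                              weights)[0]
            for d in (0.0, 0.1, 0.2, 0.4)
        ]
        assert all(a < b for a, b in zip(losses, losses[1:]))

    def test_zero_everything_zero_residual(self, weights):
        z = strain_field(np.zeros((6,) + GRID), SPACING)
        # degenerate all-zero input: residual identically zero
        op = ConstitutiveIso.__new__(ConstitutiveIso)
        op.grid_shape, op.n = GRID, N
        op.a = np.zeros((N, 6))
        op.b = np.zeros((N, 6))
        loss, *_ = op.loss_and_grads(np.ones(N), np.ones(N),
                                     np.zeros((N, 6)), weights)
        assert loss == 0.0


class TestConstitutiveTI:
    def test_batched_equals_loop_oracle(self, rng, strain, weights):
        orient = orientation_field(rng.uniform(-np.pi, np.pi, (3,) + GRID),
                                   SPACING)
        op = ConstitutiveTI(strain, orient)
        c = np.abs(rng.standard_normal((N, 5))) + 0.5
        sigma = rng.standard_normal((N, 6))
        got = op.residual(c, sigma)
        epsv = strain_to_voigt(strain)
        basis = ti_stiffness_basis()
        ang = orient.values.reshape(3, -1)
        for v in rng.choice(N, size=30, replace=False):
            B = bond_matrix(euler_rotation(EulerAngles(*ang[:, v])))
            C = B.T @ np.einsum("k,kij->ij", c[v], basis) @ B
            assert np.allclose(got[v], C @ epsv[v] - sigma[v], atol=1e-10)

    def test_zero_angles_isotropic_degenerate_matches_iso(self, strain, rng):
        lam0, mu0 = 1.1, 0.6
        orient0 = orientation_field(np.zeros((3,) + GRID), SPACING)
        ti = ConstitutiveTI(strain, orient0)
        iso = ConstitutiveIso(strain)
        sigma = rng.standard_normal((N, 6))
        c_iso = np.tile([2 * mu0 + lam0, lam0, 2 * mu0 + lam0, lam0, mu0],
                        (N, 1))
        r_ti = ti.residual(c_iso, sigma)
        r_iso = iso.residual(np.full(N, lam0), np.full(N, mu0), sigma)
        assert np.abs(r_ti - r_iso).max() < 1e-10

    def test_homogeneous_uniform_fields_zero_residual(self, rng, weights):
        # uniform strain + uniform stress consistent with a uniform TI
        # stiffness at a uniform angle -> exactly zero residual
        theta = np.deg2rad(35.0)
        ov = np.zeros((3,) + GRID)
        ov[1] = theta
        orient = orientation_field(ov, SPACING)
        c = np.array([3.1, 0.9, 1.4, 0.6, 0.5])
        B = bond_matrix(euler_rotation(EulerAngles(0, theta, 0)))
        Cg = B.T @ np.einsum("k,kij->ij", c, ti_stiffness_basis()) @ B
        eps = np.array([0.01, -0.004, 0.002, 0.001, 0.0, -0.003])
        vals = np.broadcast_to(eps[:, None, None, None], (6,) + GRID).copy()
        vals[3:] *= 0.5                       # tensor shear components
        strain_u = strain_field(vals, SPACING)
        sig = Cg @ eps
        op = ConstitutiveTI(strain_u, orient)
        loss, *_ = op.loss_and_grads(np.tile(c, (N, 1)),
                                     np.tile(sig, (N, 1)), weights)
        assert loss < 1e-25


class TestEquilibriumLoss:
    def test_uniform_zero(self):
        loss, grad = equilibrium_loss(np.ones((6,) + GRID) * 3.0, SPACING)
        assert loss < 1e-28
        assert np.abs(grad).max() < 1e-13

    def test_random_positive(self, rng):
        loss, _ = equilibrium_loss(rng.standard_normal((6,) + GRID), SPACING)
        assert loss > 0

    def test_gradient_is_adjoint(self, rng):
        sig = rng.standard_normal((6,) + GRID)
        loss, grad = equilibrium_loss(sig, SPACING)
        for _ in range(5):
            v = rng.standard_normal(sig.shape)
            eps = 1e-6
            lp, _ = equilibrium_loss(sig + eps * v, SPACING)
            lm, _ = equilibrium_loss(sig - eps * v, SPACING)
            num = (lp - lm) / (2 * eps)
            assert float((grad * v).sum()) == pytest.approx(num, rel=1e-6)


class TestBoundaryLoss:
    def test_matching_conditions_zero(self, weights):
        bc = BoundaryTractions.uniaxial(2, -0.7)
        vals = np.zeros((6,) + GRID)
        vals[2] = -0.7
        loss, grad = BoundaryLoss(bc, GRID).loss_and_grads(vals, weights)
        assert loss < 1e-28
        assert np.abs(grad).max() < 1e-14

    def test_lateral_normals_contribute_under_uniform_stress(self, weights):
        # uniform sigma_zz with free lateral faces: only the lateral
        # normal components violate their zero-traction condition
        bc = BoundaryTractions.uniaxial(2, -0.7)
        vals = np.zeros((6,) + GRID)
        vals[2] = -0.7
        vals[0] = 0.2                        # sigma_xx violates x faces
        loss, grad = BoundaryLoss(bc, GRID).loss_and_grads(vals, weights)
        assert loss > 0
        assert np.abs(grad[0][0]).max() > 0          # x- face normal
        assert np.abs(grad[2][:, :, 0]).max() == 0.0  # z- normal not constrained

    def test_doubling_weights_doubles_loss(self, rng, weights):
        bc = BoundaryTractions.uniaxial(2, -0.7)
        op = BoundaryLoss(bc, GRID)
        sig = rng.standard_normal((6,) + GRID)
        l1, _ = op.loss_and_grads(sig, weights)
        w2 = AdaptiveWeights(GRID)
        for f in w2.s_face:
            w2.s_face[f] *= np.sqrt(2.0)
        l2, _ = op.loss_and_grads(sig, w2)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)


class TestAdaptiveWeights:
    def test_zero_residual_leaves_weights(self, strain, weights):
        lam0, mu0 = 1.3, 0.7
        sig = strain_to_voigt(strain) @ assemble_isotropic_stiffness(
            IsotropicParams(lam0, mu0)).T
        op = ConstitutiveIso(strain)
        op.loss_and_grads(np.full(N, lam0), np.full(N, mu0), sig, weights)
        before = weights.s_const.copy()
        update_adaptive_weights(weights, 1e-3)
        assert np.allclose(weights.s_const, before, atol=1e-20)

    def test_hotspot_weight_grows(self, strain, weights):
        lam0, mu0 = 1.3, 0.7
        sig = strain_to_voigt(strain) @ assemble_isotropic_stiffness(
            IsotropicParams(lam0, mu0)).T
        sig[17] += 5.0
        op = ConstitutiveIso(strain)
        op.loss_and_grads(np.full(N, lam0), np.full(N, mu0), sig, weights)
        update_adaptive_weights(weights, 1e-3)
        flat = weights.s_const.reshape(-1)
        assert flat[17] > 1.0
        assert np.allclose(np.delete(flat, 17), 1.0)

    def test_weights_stay_nonnegative(self, rng):
        w = AdaptiveWeights(GRID)
        for _ in range(1000):
            w.g_const = rng.standard_normal(GRID)
            update_adaptive_weights(w, 0.01)
        assert (w.const >= 0).all()


class TestTotals:
    def test_iso_exact_solution_near_zero(self, rng):
        lam0, mu0 = 1.3, 0.7
        s0 = 0.035
        vals = np.zeros((6,) + GRID)
        C = assemble_isotropic_stiffness(IsotropicParams(lam0, mu0))
        eps = np.linalg.solve(C, [0, 0, -s0, 0, 0, 0])
        eps[3:] *= 0.5
        vals[:] = eps[:, None, None, None]
        strain_u = strain_field(vals, SPACING)
        bc = BoundaryTractions.uniaxial(2, -s0)
        total = TotalLossIso(strain_u, bc)
        out = np.zeros((8,) + GRID)
        out[0], out[1] = lam0, mu0
        out[4] = -s0
        bd, _ = total(out, AdaptiveWeights(GRID))
        assert bd.total < 1e-25

    def test_iso_violation_positive_and_components_sum(self, rng, strain):
        total = TotalLossIso(strain, BoundaryTractions.uniaxial(2, -0.035))
        out = rng.standard_normal((8,) + GRID)
        bd, _ = total(out, AdaptiveWeights(GRID))
        assert bd.constitutive > 0 and bd.equilibrium > 0 and bd.boundary > 0
        assert bd.total == pytest.approx(
            bd.constitutive + bd.equilibrium + bd.boundary)

    def test_iso_gradient_directional(self, rng, strain):
        total = TotalLossIso(strain, BoundaryTractions.uniaxial(2, -0.035))
        w = AdaptiveWeights(GRID)
        out = rng.standard_normal((8,) + GRID)
        out[:2] = np.abs(out[:2])
        bd, dout = total(out, w)
        for _ in range(3):
            v = rng.standard_normal(out.shape)
            eps = 1e-6
            bp, _ = total(out + eps * v, w)
            bm, _ = total(out - eps * v, w)
            num = (bp.total - bm.total) / (2 * eps)
            assert float((dout * v).sum()) == pytest.approx(num, rel=1e-6)

    def test_ti_mean_and_permutation(self, rng):
        strains = [strain_field(rng.standard_normal((6,) + GRID) * 0.01,
                                SPACING) for _ in range(3)]
        bcs = [BoundaryTractions.uniaxial(a, -0.05) for a in range(3)]
        orient = orientation_field(rng.uniform(-1, 1, (3,) + GRID), SPACING)
        total = TotalLossTI(strains, bcs, orient)
        c = np.abs(rng.standard_normal((5,) + GRID)) + 0.5
        sigs = [rng.standard_normal((6,) + GRID) for _ in range(3)]
        bd, _, _ = total(c, sigs, AdaptiveWeights(GRID))
        assert bd.total == pytest.approx(np.mean(
            [p.total for p in bd.per_loading]))
        perm = [2, 0, 1]
        total_p = TotalLossTI([strains[i] for i in perm],
                              [bcs[i] for i in perm], orient)
        bd_p, _, _ = total_p(c, [sigs[i] for i in perm], AdaptiveWeights(GRID))
        assert bd_p.total == pytest.approx(bd.total, rel=1e-12)

    def test_ti_identical_loadings_mean_equals_each(self, rng):
        s = strain_field(rng.standard_normal((6,) + GRID) * 0.01, SPACING)
        bc = BoundaryTractions.uniaxial(2, -0.05)
        orient = orientation_field(np.zeros((3,) + GRID), SPACING)
        c = np.abs(rng.standard_normal((5,) + GRID)) + 0.5
        sig = rng.standard_normal((6,) + GRID)
        t3 = TotalLossTI([s] * 3, [bc] * 3, orient)
        bd3, _, _ = t3(c, [sig] * 3, AdaptiveWeights(GRID))
        assert bd3.total == pytest.approx(bd3.per_loading[0].total, rel=1e-12)

    def test_ti_single_loading_rejected(self, rng):
        s = strain_field(rng.standard_normal((6,) + GRID) * 0.01, SPACING)
        orient = orientation_field(np.zeros((3,) + GRID), SPACING)
        with pytest.raises(ValueError, match="under-determine"):
            TotalLossTI([s], [BoundaryTractions.uniaxial(2, -0.05)], orient)

    def test_ti_two_loadings_allowed(self, rng):
        s = [strain_field(rng.standard_normal((6,) + GRID) * 0.01, SPACING)
             for _ in range(2)]
        bcs = [BoundaryTractions.uniaxial(a, -0.05) for a in range(2)]
        orient = orientation_field(np.zeros((3,) + GRID), SPACING)
        total = TotalLossTI(s, bcs, orient)
        c = np.abs(np.ones((5,) + GRID))
        sigs = [np.zeros((6,) + GRID)] * 2
        bd, _, _ = total(c, sigs, AdaptiveWeights(GRID))
        assert bd.total > 0
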