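"""NITI constitutive model: degeneracies, covariance, derived stiffness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anisomre import material as m

K = 1.0e7
CONSTS = m.PhysicsConstants(bulk_modulus=K)


def bond_matrix(R):
    """Bond stress-transformation matrix for Voigt stiffness: C' = M C M^T.

    Independent oracle for the tensor-rotation route used by the
    implementation.
    """
    M = np.zeros((6, 6))
    pairs = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    for a, (i, j) in enumerate(pairs):
        for b, (k, l) in enumerate(pairs):
            if b < 3:
                M[a, b] = R[i, k] * R[j, k]
            else:
                M[a, b] = R[i, k] * R[j, l] + R[i, l] * R[j, k]
    return M


class TestAssembleStiffness:
    def test_isotropic_degeneracy(self):
        G = m.ComplexShearModulus(2500.0, 1000.0)
        p = m.NITIParameters(G, 0.0, 0.0, np.array([0.6, 0.0, 0.8]))
        C = m.assemble_stiffness(p, CONSTS).voigt
        C_iso = m.isotropic_voigt(G.complex, K)
        assert np.max(np.abs(C - C_iso)) / np.max(np.abs(C_iso)) < 1e-9

    def test_axis_shear_moduli(self):
        G = m.ComplexShearModulus(2500.0, 1000.0)
        C = m.assemble_stiffness(m.NITIParameters(G, 0.35, 1.0), CONSTS).voigt
        # fiber along z: axial shear blocks carry G1 = G2 (1+phi), in-plane G2
        assert C[3, 3] == pytest.approx(G.complex * 1.35, rel=1e-12)
        assert C[4, 4] == pytest.approx(G.complex * 1.35, rel=1e-12)
        assert C[5, 5] == pytest.approx(G.complex, rel=1e-12)

    def test_rotation_covariance_bond_oracle(self):
        rng = np.random.default_rng(7)
        G = m.ComplexShearModulus(2500.0, 800.0)
        C0 = m.assemble_stiffness(m.NITIParameters(G, 0.3, 1.0), CONSTS).voigt
        for _ in range(10):
            f = rng.normal(size=3)
            f /= np.linalg.norm(f)
            R = m.rotation_to_axis(f)
            C_rot = m.assemble_stiffness(m.NITIParameters(G, 0.3, 1.0, f), CONSTS).voigt
            MB = bond_matrix(R)
            C_bond = MB @ C0 @ MB.T
            assert np.max(np.abs(C_rot - C_bond)) / np.max(np.abs(C_bond)) < 1e-9

    def test_symmetry(self):
        C = m.assemble_stiffness(
            m.NITIParameters(m.ComplexShearModulus(3000.0, 500.0), 0.2, 0.9,
                             np.array([1.0, 1.0, 1.0]) / np.sqrt(3)),
            CONSTS,
        ).voigt
        assert np.max(np.abs(C - C.T)) == 0.0

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="storage"):
            m.ComplexShearModulus(-1.0, 0.0)
        with pytest.raises(ValueError, match="phi"):
            m.NITIParameters(m.ComplexShearModulus(1000.0), -1.2, 0.0)
        with pytest.raises(ValueError, match="zeta"):
            m.NITIParameters(m.ComplexShearModulus(1000.0), 0.0, -0.8)
        with pytest.raises(ValueError, match="unit"):
            m.NITIParameters(m.ComplexShearModulus(1000.0), 0.0, 0.0, np.array([1.0, 1.0, 0.0]))
        with pytest.raises(ValueError, match="bulk"):
            m.assemble_stiffness(
                m.NITIParameters(m.ComplexShearModulus(3000.0), 0.0, 0.0),
                m.PhysicsConstants(bulk_modulus=1e5),
            )


class TestShearStiffness:
    def test_lossless_collapses_to_storage(self):
        assert m.shear_stiffness(m.ComplexShearModulus(3000.0, 0.0)) == pytest.approx(3000.0)

    def test_hand_evaluated_example(self):
        # 2 |G|^2 / (G' + |G|) at G = 2500 + 1000j
        mag = np.hypot(2500.0, 1000.0)
        expected = 2 * mag**2 / (2500.0 + mag)
        got = m.shear_stiffness(m.ComplexShearModulus(2500.0, 1000.0))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2792.44, abs=0.01)

    @given(
        gp=st.floats(100.0, 9000.0),
        # the 2 G' upper bound holds for loss ratios below (1+sqrt 5)/2;
        # tissue damping at 50 Hz sits well inside that regime
        ratio=st.floats(0.0, 1.2),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_algebraic_bounds_and_monotonicity(self, gp, ratio):
        mu = m.shear_stiffness(m.ComplexShearModulus(gp, ratio * gp))
        assert gp - 1e-9 <= mu <= 2 * gp + 1e-9
        mu_more_loss = m.shear_stiffness(m.ComplexShearModulus(gp, (ratio + 0.1) * gp))
        assert mu_more_loss > mu


class TestParallelStiffness:
    @pytest.mark.parametrize(
        "mu2,phi,expected",
        [
            (2.79, 0.0, 2.79),
            (2.79, 0.35, 3.7665),  # voxelwise mu1 = mu2 (1 + phi)
            (2.62, -0.07, 2.4366),  # negative anisotropy: mu1 < mu2
        ],
    )
    def test_values(self, mu2, phi, expected):
        assert m.parallel_stiffness(mu2, phi) == pytest.approx(expected, rel=1e-12)

    def test_rejects_phi_at_minus_one(self):
        with pytest.raises(ValueError):
            m.parallel_stiffness(2.5, -1.0)


class TestWaveSpeeds:
    def test_isotropic_closed_form(self):
        p = m.NITIParameters(m.ComplexShearModulus(3000.0), 0.0, 0.0)
        for d in ([1, 0, 0], [0, 1, 0], [0.3, 0.5, 0.9]):
            v = m.wave_speeds(p, CONSTS, d)
            assert v[0] == pytest.approx(np.sqrt(3.0), rel=1e-9)
            assert v[1] == pytest.approx(np.sqrt(3.0), rel=1e-9)
            assert v[2] > 50.0  # quasi-longitudinal, bulk-dominated

    def test_perpendicular_direction_fiber_polarized_mode(self):
        p = m.NITIParameters(m.ComplexShearModulus(3000.0), 0.35, 1.0)
        v = m.wave_speeds(p, CONSTS, [1.0, 0.0, 0.0])
        assert v[0] == pytest.approx(np.sqrt(3.0), rel=1e-6)  # in-plane shear, G2
        assert v[1] == pytest.approx(np.sqrt(3.0 * 1.35), rel=1e-6)  # fiber shear, G1

    def test_along_fiber_shear_degeneracy(self):
        p = m.NITIParameters(m.ComplexShearModulus(3000.0), 0.35, 1.0)
        v = m.wave_speeds(p, CONSTS, [0.0, 0.0, 1.0])
        assert v[0] == pytest.approx(v[1], rel=1e-9)

    def test_zero_direction_rejected(self):
        p = m.NITIParameters(m.ComplexShearModulus(3000.0), 0.0, 0.0)
        with pytest.raises(ValueError):
            m.wave_speeds(p, CONSTS, [0.0, 0.0, 0.0])

    def test_brute_force_christoffel_agreement(self):
        """Implementation vs an independent loop-built Christoffel tensor."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            mu = rng.uniform(500, 8000)
            phi = rng.uniform(-0.6, 1.8)
            zeta = rng.uniform(-0.6, 3.5)
            f = rng.normal(size=3)
            f /= np.linalg.norm(f)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            p = m.NITIParameters(m.ComplexShearModulus(mu, 0.0), phi, zeta, f)
            v = m.wave_speeds(p, CONSTS, d)
            C = m.assemble_stiffness(p, CONSTS).tensor().real
            gamma = np.zeros((3, 3))
            for i in range(3):
                for k in range(3):
                    for j in range(3):
                        for l in range(3):
                            gamma[i, k] += d[j] * C[i, j, k, l] * d[l]
            ref = np.sort(np.sqrt(np.clip(np.linalg.eigvalsh(gamma), 0, None) / 1000.0))
            assert np.allclose(v, ref, rtol=1e-8)


def test_storage_from_stiffness_round_trip():
    for eta in (0.0, 0.3, 1.0):
        gp = m.storage_from_stiffness(2800.0, eta)
        assert m.shear_stiffness(complex(gp, eta * gp)) == pytest.approx(2800.0, rel=1e-12)
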