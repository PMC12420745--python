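"""Strain energies, kinematics, regularizers, growth split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nodereg as nr
from nodereg.mechanics import dpsi_dF, dreg_dF

ALL_KINDS = ["stvk", "neo_hookean", "ablation_poly"]


class TestKinematics:
    def test_identity(self):
        k = nr.kinematics(np.eye(3))
        assert np.allclose(k["C"], np.eye(3))
        assert np.allclose(k["E"], 0.0)
        assert k["I1"] == pytest.approx(3.0)
        assert k["I2"] == pytest.approx(3.0)
        assert k["J"] == pytest.approx(1.0)

    def test_diagonal_stretch(self):
        k = nr.kinematics(np.diag([2.0, 1.0, 1.0]))
        assert np.allclose(k["C"], np.diag([4.0, 1.0, 1.0]))
        assert k["I1"] == pytest.approx(6.0)
        assert k["J"] == pytest.approx(2.0)

    def test_second_invariant_matches_eigen_oracle(self, rng):
        F = np.eye(3) + 0.3 * rng.standard_normal((8, 3, 3))
        k = nr.kinematics(F)
        lam = np.linalg.eigvalsh(k["C"])
        oracle = 0.5 * (lam.sum(axis=1) ** 2 - (lam ** 2).sum(axis=1))
        assert np.allclose(k["I2"], oracle, atol=1e-10)


class TestPsi:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_zero_at_identity(self, kind):
        for d in (2, 3):
            assert nr.psi(nr.Material(kind), np.eye(d)) == pytest.approx(
                0.0, abs=1e-14)

    def test_hand_computed_values(self):
        F = np.diag([2.0, 1.0, 1.0])
        assert nr.psi(nr.Material("stvk"), F) == pytest.approx(3.375)
        assert nr.psi(nr.Material("neo_hookean"), F) == pytest.approx(
            1.04708, abs=1e-5)
        assert nr.psi(nr.Material("ablation_poly"),
                      np.diag([1.1, 1.0, 1.0])) == pytest.approx(0.3191)

    def test_neo_hookean_rejects_noninvertible(self):
        with pytest.raises(ValueError, match="non-invertible"):
            nr.psi(nr.Material("neo_hookean"), np.diag([-1.0, 1.0]))

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_frame_indifference(self, kind, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        m = nr.Material(kind)
        assert nr.psi(m, Q @ F) == pytest.approx(nr.psi(m, F), abs=1e-10)

    @pytest.mark.parametrize("kind", ["stvk", "neo_hookean"])
    def test_nonnegative_near_identity(self, kind, rng):
        # the ablation polynomial is excluded: its linear (I1-3) and
        # (I2-3)/12 terms make the identity a non-stationary zero, so it
        # goes negative under slight compression by construction
        m = nr.Material(kind)
        F = np.eye(3) + 0.1 * (rng.random((50, 3, 3)) - 0.5) / 1.5
        assert np.all(nr.psi(m, F) >= -1e-12)

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_dpsi_matches_finite_differences(self, kind, rng):
        m = nr.Material(kind)
        F = np.eye(2) + 0.2 * rng.standard_normal((2, 2))
        _, G = dpsi_dF(m, F)
        h = 1e-6
        for i in range(2):
            for j in range(2):
                E = np.zeros((2, 2))
                E[i, j] = h
                fd = (nr.psi(m, F + E) - nr.psi(m, F - E)) / (2 * h)
                assert G[i, j] == pytest.approx(fd, abs=1e-5)

    def test_literal_stvk_trace_flag(self):
        F = np.diag([2.0, 1.0, 1.0])
        lit = nr.Material("stvk", stvk_literal_trace=True)
        assert nr.psi(lit, F) == pytest.approx(0.5 * 1.5 + 2.25)


class TestRegularizer:
    def test_fnorm_logj_values(self):
        assert nr.regularizer("fnorm_logJ", nr.Material(), np.eye(2)) \
            == pytest.approx(2.0)
        assert nr.regularizer("fnorm_logJ", nr.Material(),
                              np.diag([2.0, 1.0])) == pytest.approx(
            5.0 + np.log(2) ** 2)

    def test_strain_energy_delegates_to_psi(self):
        m = nr.Material("stvk")
        F = np.diag([1.3, 0.9])
        assert nr.regularizer("strain_energy", m, F) == nr.psi(m, F)

    def test_gradient_matches_fd(self, rng):
        F = np.eye(2) + 0.2 * rng.standard_normal((2, 2))
        _, G = dreg_dF("fnorm_logJ", nr.Material(), F)
        h = 1e-6
        for i in range(2):
            for j in range(2):
                E = np.zeros((2, 2))
                E[i, j] = h
                fd = (nr.regularizer("fnorm_logJ", nr.Material(), F + E)
                      - nr.regularizer("fnorm_logJ", nr.Material(), F - E)) \
                    / (2 * h)
                assert G[i, j] == pytest.approx(fd, abs=1e-5)

    def test_nonpositive_jacobian_rejected(self):
        with pytest.raises(ValueError):
            nr.regularizer("fnorm_logJ", nr.Material(), np.diag([-1.0, 1.0]))


class TestGrowth:
    def test_exact_absorption_of_uniform_stretch(self):
        g = nr.GrowthModel(kappa=np.log(2.0), mode="growth", t=1.0)
        Fe = nr.elastic_part(2.0 * np.eye(3), g)
        assert np.allclose(Fe, np.eye(3))
        assert nr.psi(nr.Material("stvk"), Fe) == pytest.approx(0.0)

    def test_zero_rate_is_identity_split(self, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        g = nr.GrowthModel(kappa=0.0, mode="growth")
        assert np.allclose(nr.elastic_part(F, g), F)

    def test_shrinkage_jacobian_reported_value(self):
        g = nr.GrowthModel(kappa=0.013111, mode="shrinkage", t=1.0)
        assert g.growth_jacobian(3) == pytest.approx(0.961431, abs=1e-5)

    @given(st.floats(0.0, 0.5), st.sampled_from(["growth", "shrinkage"]))
    @settings(max_examples=25, deadline=None)
    def test_determinant_split_is_exact(self, kappa, mode):
        rng = np.random.default_rng(1)
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        g = nr.GrowthModel(kappa=kappa, mode=mode)
        Fe = nr.elastic_part(F, g)
        assert np.linalg.det(Fe) * g.growth_jacobian(3) == pytest.approx(
            np.linalg.det(F), rel=1e-12)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            nr.GrowthModel(kappa=0.1, mode="sideways")
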