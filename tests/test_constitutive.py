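"""Material law: invariants, stresses, relaxation, parameter conversions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from softshock.constitutive import (
    ACConfig,
    MaterialQLV,
    ac_pressure,
    convert_elastic_params,
    dev_lagrangian,
    deviatoric_drive,
    elastic_stress_bar,
    gelatin_tripathi,
    invariants,
    relax_update,
    rivlin_from_fourth_order,
    total_stress,
)
from softshock.errors import ConfigError, ElementInversionError


class TestInvariants:
    @pytest.mark.parametrize(
        "C, expected",
        [
            (np.eye(3), (3.0, 3.0)),
            (np.diag([4.0, 1.0, 1.0]), (6.0, 9.0)),
        ],
    )
    def test_closed_forms(self, C, expected):
        I1, I2 = invariants(C)
        assert I1 == pytest.approx(expected[0])
        assert I2 == pytest.approx(expected[1])

    def test_simple_shear(self):
        gamma = 0.5
        F = np.eye(3)
        F[2, 0] = gamma
        I1, _ = invariants(F.T @ F)
        assert I1 == pytest.approx(3.0 + gamma ** 2)

    def test_rejects_asymmetric(self):
        C = np.eye(3)
        C[0, 1] = 1e-3
        with pytest.raises(ConfigError):
            invariants(C)


class TestElasticStress:
    def test_identity_state(self, gelatin):
        S = elastic_stress_bar(np.eye(3), gelatin)
        expected = 2.0 * (gelatin.C10 + 2.0 * gelatin.C01) * np.eye(3)
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_neo_hookean_is_isotropic_pressure(self):
        mat = MaterialQLV(rho0=1000.0, C10=500.0)
        gamma = 0.4
        F = np.eye(3)
        F[2, 0] = gamma
        C = F.T @ F
        S = elastic_stress_bar(C, mat)
        np.testing.assert_allclose(S, 2.0 * mat.C10 * np.eye(3), atol=1e-12)

    def test_matches_energy_derivative(self, gelatin_elastic):
        # central-difference oracle 2 dW/dC of the Mooney-Rivlin/Yeoh energy
        mat = gelatin_elastic
        gamma = 0.3
        F = np.eye(3)
        F[2, 0] = gamma
        C = F.T @ F  # simple shear is unimodular

        def W(Cm):
            I1 = np.trace(Cm)
            I2 = 0.5 * (I1 ** 2 - np.trace(Cm @ Cm))
            return (mat.C10 * (I1 - 3) + mat.C01 * (I2 - 3)
                    + mat.C20 * (I1 - 3) ** 2)

        S = elastic_stress_bar(C, mat)
        h = 1e-7
        for i in range(3):
            for j in range(3):
                dC = np.zeros((3, 3))
                dC[i, j] += 0.5 * h
                dC[j, i] += 0.5 * h  # symmetric perturbation
                deriv = (W(C + dC) - W(C - dC)) / (2 * h)
                assert 2 * deriv == pytest.approx(S[i, j], rel=1e-6, abs=1e-8)


class TestDevLagrangian:
    def test_identity_projects_to_zero(self):
        np.testing.assert_allclose(
            dev_lagrangian(np.eye(3), np.eye(3)), np.zeros((3, 3)), atol=1e-15
        )

    def test_projection_is_idempotent_and_orthogonal(self, rng):
        S = rng.standard_normal((3, 3))
        S = 0.5 * (S + S.T)
        C = np.diag([2.0, 1.0, 1.0])
        R = dev_lagrangian(S, C)
        assert abs(np.tensordot(R, C)) < 1e-12 * np.abs(S).max()
        np.testing.assert_allclose(dev_lagrangian(R, C), R, atol=1e-12)


class TestACPressure:
    def test_reference_and_compression(self, gelatin, ac09):
        assert ac_pressure(1.0, ac09, gelatin) == 0.0
        assert ac_pressure(0.99, ac09, gelatin) == pytest.approx(29.822, rel=1e-4)

    def test_odd_about_reference(self, gelatin, ac09):
        for J in (0.9, 0.97, 1.05):
            assert ac_pressure(J, ac09, gelatin) + ac_pressure(
                2.0 - J, ac09, gelatin
            ) == pytest.approx(0.0, abs=1e-9)

    def test_inverted_element_rejected(self, gelatin, ac09):
        with pytest.raises(ElementInversionError):
            ac_pressure(-0.1, ac09, gelatin)


class TestTotalStress:
    def test_reference_state_stress_free(self, gelatin, ac09):
        S, P = total_stress(np.eye(3), np.zeros((3, 3, 3)), ac09, gelatin)
        assert np.abs(S).max() == 0.0
        assert np.abs(P).max() == 0.0

    def test_memory_only_contribution(self, gelatin, ac09, rng):
        S_v = rng.standard_normal((3, 3, 3))
        S_v = 0.5 * (S_v + np.swapaxes(S_v, -1, -2))
        S, _ = total_stress(np.eye(3), S_v, ac09, gelatin)
        np.testing.assert_allclose(S, -S_v.sum(axis=0), atol=1e-12)

    @pytest.mark.parametrize("gamma", [0.05, 0.1])
    def test_antiplane_shear_series(self, gelatin_elastic, ac09, gamma):
        # fast elastic limit: P31 = mu gamma (1 + 2 beta gamma^2 / 3) + O(g^5)
        mat = gelatin_elastic
        F = np.eye(3)
        F[2, 0] = gamma
        _, P = total_stress(F, None, ac09, mat)
        target = mat.mu * (gamma + (2.0 / 3.0) * mat.beta * gamma ** 3)
        assert abs(P[2, 0] - target) < 5.0 * mat.mu * gamma ** 5

    def test_first_pk_is_energy_gradient(self, gelatin_elastic, ac09, rng):
        # AC energy U(J) + W_bar(C_bar); central differences h = 1e-6
        mat = gelatin_elastic
        K = ac09.bulk_modulus(mat)

        def W(F):
            J = np.linalg.det(F)
            Cb = J ** (-2.0 / 3.0) * (F.T @ F)
            I1 = np.trace(Cb)
            I2 = 0.5 * (I1 ** 2 - np.trace(Cb @ Cb))
            return (0.5 * K * (J - 1) ** 2 + mat.C10 * (I1 - 3)
                    + mat.C01 * (I2 - 3) + mat.C20 * (I1 - 3) ** 2)

        for _ in range(20):
            F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            F = F / np.linalg.det(F) ** (1 / 3)  # unimodular
            _, P = total_stress(F, None, ac09, mat)
            h = 1e-6
            for i in range(3):
                for j in range(3):
                    dF = np.zeros((3, 3))
                    dF[i, j] = h
                    deriv = (W(F + dF) - W(F - dF)) / (2 * h)
                    assert deriv == pytest.approx(
                        P[i, j], rel=1e-5, abs=1e-5 * mat.mu
                    )

    def test_incompressible_limit_volumetric_term_vanishes(self, gelatin_elastic):
        # at det F = 1 the pressure term is inactive for every epsilon
        F = np.eye(3)
        F[1, 0] = 0.25
        stresses = [
            total_stress(F, None, ACConfig(eps), gelatin_elastic)[1]
            for eps in (0.9, 1e-4)
        ]
        np.testing.assert_allclose(stresses[0], stresses[1], atol=1e-8)

    def test_inverted_element_rejected(self, gelatin, ac09):
        with pytest.raises(ElementInversionError):
            total_stress(-np.eye(3), None, ac09, gelatin)


class TestRelaxation:
    def test_zero_dt_is_identity(self, gelatin, rng):
        S_v = rng.standard_normal((3, 3, 3))
        drive = rng.standard_normal((3, 3))
        np.testing.assert_array_equal(
            relax_update(S_v, drive, 0.0, gelatin), S_v
        )

    def test_equilibrium_fixed_point(self, gelatin, rng):
        drive = rng.standard_normal((3, 3))
        drive = 0.5 * (drive + drive.T)
        S_v = np.array([g * drive for g in gelatin.g])
        for dt in (1e-4, 1e-2, 10.0):
            np.testing.assert_allclose(
                relax_update(S_v, drive, dt, gelatin), S_v, rtol=1e-13, atol=1e-13
            )

    def test_infinite_time_reaches_equilibrium(self, gelatin, rng):
        S_v = rng.standard_normal((3, 3, 3))
        drive = rng.standard_normal((3, 3))
        out = relax_update(S_v, drive, 1e9, gelatin)
        expected = np.array([g * drive for g in gelatin.g])
        np.testing.assert_array_equal(out, expected)

    def test_matches_ode_integration(self, gelatin, rng):
        # adaptive high-accuracy integration of the relaxation ODE
        drive = rng.standard_normal((3, 3))
        drive = 0.5 * (drive + drive.T)
        S0 = rng.standard_normal((3, 3))
        S0 = 0.5 * (S0 + S0.T)
        dt = 1e-3
        for gl, wl in zip(gelatin.g, gelatin.omega):
            sol = solve_ivp(
                lambda t, y: wl * (gl * drive.ravel() - y),
                (0.0, dt), S0.ravel(), rtol=1e-12, atol=1e-14,
            )
            mat1 = MaterialQLV(rho0=1000.0, C10=500.0, g=(gl,), omega=(wl,))
            ours = relax_update(S0[None], drive, dt, mat1)[0]
            np.testing.assert_allclose(
                ours.ravel(), sol.y[:, -1], rtol=1e-9, atol=1e-12
            )

    def test_trace_free_drive_preserved(self, gelatin, rng):
        drive = rng.standard_normal((3, 3))
        drive = 0.5 * (drive + drive.T)
        drive -= np.trace(drive) / 3 * np.eye(3)
        S_v = np.array([0.3 * drive, -0.1 * drive, 0.7 * drive])
        out = relax_update(S_v, drive, 5e-3, gelatin)
        for k in range(3):
            assert abs(np.trace(out[k])) < 1e-14

    def test_linear_branch_drive_is_trace_free(self, ac09):
        mat = gelatin_tripathi(linear=True)
        F = np.eye(3) + 1e-3 * np.array(
            [[0.3, 0.1, 0.0], [0.2, -0.4, 0.5], [0.0, 0.1, 0.1]]
        )
        drive = deviatoric_drive(F, ac09, mat)
        assert abs(np.trace(drive)) < 1e-12 * np.abs(drive).max()


class TestParameterConversions:
    def test_gelatin_coefficients(self):
        C10, C20 = convert_elastic_params(2684.0, 4.4, 0.0)
        assert C10 == pytest.approx(1342.0)
        assert C20 == pytest.approx(1968.27, abs=0.5)

    def test_neo_hookean_limit(self):
        _, C20 = convert_elastic_params(2000.0, 0.0, 0.0)
        assert C20 == 0.0

    def test_round_trip_through_material(self):
        C10, C20 = convert_elastic_params(2684.0, 4.4, 0.0)
        mat = MaterialQLV(rho0=1000.0, C10=C10, C01=0.0, C20=C20)
        assert mat.mu == pytest.approx(2684.0)
        assert mat.beta == pytest.approx(4.4)

    @given(
        mu=st.floats(500.0, 5000.0),
        A=st.floats(-5000.0, 5000.0),
        D=st.floats(-5000.0, 5000.0),
    )
    def test_fourth_order_links_consistent_with_both_beta_forms(self, mu, A, D):
        C10, C01, C20 = rivlin_from_fourth_order(mu, A, D)
        assert 2 * (C10 + C01) == pytest.approx(mu, rel=1e-12)
        beta_rivlin = 3 * C20 / (C10 + C01)
        beta_fourth = 1.5 * (mu + A / 2 + D) / mu
        assert beta_rivlin == pytest.approx(beta_fourth, rel=1e-9, abs=1e-9)


class TestMaterialValidation:
    def test_gelatin_derived_constants(self, gelatin):
        assert gelatin.mu == pytest.approx(2684.0)
        assert gelatin.beta == pytest.approx(4.4)
        assert gelatin.c_inf == pytest.approx(1.638, abs=5e-4)
        assert gelatin.c0 == pytest.approx(1.3596, abs=5e-4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rho0=-1.0, C10=500.0),
            dict(rho0=1000.0, C10=-1.0),
            dict(rho0=1000.0, C10=500.0, g=(0.5, 0.6), omega=(1.0, 1.0)),
            dict(rho0=1000.0, C10=500.0, g=(1.2,), omega=(1.0,)),
            dict(rho0=1000.0, C10=500.0, g=(0.1,), omega=(-1.0,)),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            MaterialQLV(**kwargs)

    def test_ac_policy_window(self):
        ac = ACConfig.from_policy(4.0, 0.3, 1e-3, 1.0)
        assert ac.epsilon == pytest.approx(4.0 * (1e-3) ** 0.3)
        with pytest.raises(ConfigError):
            ACConfig.from_policy(4.0, 2.0, 1e-3, 1.0)

    def test_poisson_ratio(self):
        # nu = (3 - 2 eps) / (2 (3 + eps)), i.e. 1/2 in the incompressible limit
        assert ACConfig(0.02).poisson_ratio == pytest.approx(0.49, abs=0.005)
        assert ACConfig(0.1).poisson_ratio == pytest.approx(0.45, abs=0.005)
        assert ACConfig(1e-9).poisson_ratio == pytest.approx(0.5, abs=1e-6)
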