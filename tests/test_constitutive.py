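"""Ogden hyper-viscoelastic material: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retractsim.constitutive import (LinearElasticMaterial, OgdenPronyMaterial,
                                     cauchy_from_pk2,
                                     uniaxial_incompressible_cauchy)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestRelaxationModulus:
    def test_endpoints_from_swine_parameters(self, material):
        assert material.relaxation_modulus(0.0) == pytest.approx(842.0)
        assert material.relaxation_modulus(1e9) == pytest.approx(
            842.0 * (1 - 0.450 - 0.365))
        assert material.relaxation_modulus(1e9) == pytest.approx(155.77)

    def test_intermediate_value(self, material):
        # direct numeric evaluation of the Prony sum at t = tau_1
        expect = 842.0 * (1 - 0.450 * (1 - np.exp(-1.0))
                          - 0.365 * (1 - np.exp(-0.5 / 50.0)))
        assert material.relaxation_modulus(0.5) == pytest.approx(expect)
        assert material.relaxation_modulus(0.5) == pytest.approx(599.4, abs=0.1)

    def test_monotone_nonincreasing_on_log_grid(self, material):
        t = np.logspace(-3, 4, 200)
        mu = material.relaxation_modulus(t)
        assert np.all(np.diff(mu) <= 1e-12)
        assert mu[0] <= material.mu0

    def test_negative_time_rejected(self, material):
        with pytest.raises(ValueError):
            material.relaxation_modulus(-0.1)

    @given(gs=st.lists(st.floats(0.01, 0.4), min_size=1, max_size=3),
           mu0=st.floats(10.0, 5000.0))
    @settings(max_examples=25, deadline=None)
    def test_limit_is_long_term_modulus(self, gs, mu0):
        if sum(gs) >= 0.99:
            return
        mat = OgdenPronyMaterial(mu0=mu0, alpha=-4.7,
                                 prony=tuple((0.5 * (k + 1), g)
                                             for k, g in enumerate(gs)))
        assert mat.relaxation_modulus(1e9) == pytest.approx(
            mu0 * (1 - sum(gs)), rel=1e-9)


class TestEnergyDensity:
    def test_zero_at_reference(self, material):
        assert material.energy_density([1.0, 1.0, 1.0]) == 0.0

    def test_permutation_invariance(self, material):
        w = material.energy_density([1.2, 0.9, 1.05])
        for perm in ([0.9, 1.2, 1.05], [1.05, 0.9, 1.2]):
            assert material.energy_density(perm) == pytest.approx(w)

    def test_isochoric_oracle(self, material):
        # isochoric stretch -> closed-form one-term Ogden value
        lam = 1.2
        stretches = [lam, lam**-0.5, lam**-0.5]
        oracle = (2 * 842.0 / (-4.7) ** 2) * (
            lam**-4.7 + 2 * (lam**-0.5) ** -4.7 - 3)
        assert material.energy_density(stretches) == pytest.approx(oracle)

    def test_nonnegative_near_reference(self, material):
        rng = np.random.default_rng(0)
        lam = 1.0 + rng.uniform(-0.2, 0.2, (200, 3))
        assert np.all(material.energy_density(lam) >= 0)

    def test_nonpositive_stretch_rejected(self, material):
        with pytest.raises(ValueError):
            material.energy_density([1.0, -0.5, 1.0])


class TestStress:
    def test_zero_at_identity(self, material):
        S, state = material.stress(np.eye(3), dt=5.0)
        assert np.allclose(S, 0.0, atol=1e-12)
        assert np.allclose(state.h, 0.0)

    def test_uniaxial_instantaneous_oracle(self, material):
        lam = 1.1
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        sig, _ = material.stress(F, dt=0.0, measure="cauchy")
        oracle = uniaxial_incompressible_cauchy(842.0, -4.7, lam)
        assert sig[0, 0] - sig[2, 2] == pytest.approx(oracle, rel=1e-9)
        assert oracle == pytest.approx(219.3, abs=0.1)

    def test_uniaxial_matches_energy_differentiation(self, material):
        # central difference of W along an incompressible uniaxial path
        lam, h = 1.1, 1e-6
        def W(x):
            return material.energy_density([x, x**-0.5, x**-0.5])
        dW = (W(lam + h) - W(lam - h)) / (2 * h)
        # sigma_axial - sigma_lateral = lam * dW/dlam at J = 1
        oracle = uniaxial_incompressible_cauchy(842.0, -4.7, lam)
        assert lam * dW == pytest.approx(oracle, rel=1e-6)

    def test_frame_indifference(self, material):
        rng = np.random.default_rng(4)
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        sig, _ = material.stress(F, dt=0.0, measure="cauchy")
        for _ in range(5):
            R = _random_rotation(rng)
            sig_r, _ = material.stress(R @ F, dt=0.0, measure="cauchy")
            assert np.allclose(sig_r, R @ sig @ R.T, atol=1e-10 * 842)

    def test_relaxation_to_long_term_ratio(self, material):
        F = np.diag([1.1, 1.1**-0.5, 1.1**-0.5])
        C = F.T @ F
        s_iso, s_vol = material._pk2_parts(C)
        state = material.fresh_state()
        S0, h, s0 = material.pk2_update(C, state, 0.0)
        material.commit(state, h, s0, 0.0)
        for _ in range(400):
            S, h, s0 = material.pk2_update(C, state, 2.0)
            material.commit(state, h, s0, 2.0)
        ratio = (S - s_vol)[0, 0] / s_iso[0, 0]
        assert ratio == pytest.approx(1 - 0.450 - 0.365, rel=1e-3)

    def test_inverted_gradient_rejected(self, material):
        with pytest.raises(ValueError):
            material.stress(np.diag([-1.0, 1.0, 1.0]))

    @given(mu0=st.floats(50.0, 3000.0), alpha=st.floats(-8.0, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_reference_state_stress_free(self, mu0, alpha):
        if abs(alpha) < 0.1:
            return
        mat = OgdenPronyMaterial(mu0=mu0, alpha=alpha)
        S, _ = mat.stress(np.eye(3))
        assert np.allclose(S, 0.0, atol=1e-9 * mu0)
        assert mat.energy_density([1, 1, 1]) == 0.0


class TestTangent:
    @pytest.mark.parametrize("dt", [0.0, 3.0])
    def test_matches_finite_differences(self, material, dt):
        rng = np.random.default_rng(7)
        F = np.eye(3) + 0.08 * rng.normal(size=(3, 3))
        C = F.T @ F
        state = material.fresh_state()
        D = material.tangent_dSdC(C, state, dt)
        h = 1e-6
        rng2 = np.random.default_rng(8)
        for _ in range(6):  # directional derivatives along random sym. dC
            dC = rng2.normal(size=(3, 3))
            dC = dC + dC.T
            Sp, _, _ = material.pk2_update(C + h * dC, state, dt)
            Sm, _, _ = material.pk2_update(C - h * dC, state, dt)
            fd = (Sp - Sm) / (2 * h)
            pred = np.einsum("ijkl,kl->ij", D, dC)
            assert np.allclose(pred, fd, atol=1e-4 * np.abs(fd).max())

    def test_minor_symmetry_and_major_symmetry_at_identity(self, material):
        state = material.fresh_state()
        D = material.tangent_dSdC(np.eye(3), state, 0.0)
        assert np.allclose(D, D.transpose(0, 1, 3, 2), atol=1e-6 * 842)
        assert np.allclose(D, D.transpose(2, 3, 0, 1), atol=1e-6 * 842)

    def test_linear_elastic_tangent_constant(self):
        mat = LinearElasticMaterial(mu=842.0, poisson=0.45)
        st1 = mat.fresh_state()
        D1 = mat.tangent_dSdC(np.eye(3), st1, 0.0)
        F = np.eye(3) + 0.2 * np.random.default_rng(0).normal(size=(3, 3))
        D2 = mat.tangent_dSdC(F.T @ F, st1, 1.0)
        assert np.allclose(D1, D2)


class TestPronyRecursion:
    def test_matches_convolution_quadrature(self, material):
        """Exponential recursion vs brute-force hereditary integral."""
        rng = np.random.default_rng(11)
        T, n = 20.0, 1000
        ts = np.linspace(0, T, n + 1)
        A = rng.normal(0, 0.04, (3, 3))
        B = rng.normal(0, 0.04, (3, 3))

        def F_of(t):
            return np.eye(3) + A * np.sin(t / 3.0) + B * (1 - np.cos(t / 5.0))

        state = material.fresh_state()
        for i in range(1, n + 1):
            C = F_of(ts[i]).T @ F_of(ts[i])
            S, h, s0 = material.pk2_update(C, state, T / n)
            material.commit(state, h, s0, T / n)

        s_iso_hist = np.array([
            material._pk2_parts(F_of(t).T @ F_of(t))[0] for t in ts])
        ds = np.diff(s_iso_hist, axis=0)
        mid = (ts[:-1] + ts[1:]) / 2
        S_bf = s_iso_hist[-1].copy()
        for tau, g in material.prony:
            S_bf -= g * np.einsum("q,qij->ij",
                                  1 - np.exp(-(T - mid) / tau), ds)
        _, s_vol = material._pk2_parts(F_of(T).T @ F_of(T))
        err = np.abs((S - s_vol) - S_bf).max() / np.abs(S_bf).max()
        assert err < 0.005

    def test_history_starts_at_zero_and_is_deterministic(self, material):
        state = material.fresh_state()
        assert np.allclose(state.h, 0.0)
        F = np.diag([1.05, 1.0, 0.98])
        S1, st1 = material.stress(F, material.fresh_state(), dt=1.0,
                                  update=True)
        S2, st2 = material.stress(F, material.fresh_state(), dt=1.0,
                                  update=True)
        assert np.array_equal(S1, S2)
        assert np.array_equal(st1.h, st2.h)


class TestParameterValidation:
    @pytest.mark.parametrize("kw", [
        {"mu0": -1.0}, {"alpha": 0.0},
        {"prony": ((-0.5, 0.1),)}, {"prony": ((0.5, -0.1),)},
        {"prony": ((0.5, 0.6), (5.0, 0.5))}, {"poisson": 0.5},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            OgdenPronyMaterial(**kw)
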