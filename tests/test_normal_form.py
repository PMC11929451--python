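"""Amplitude equations: coefficient structure, symmetries, attractors."""

import numpy as np
import pytest

from vortexwell.linear_stability import growth_rate
from vortexwell.normal_form import (
    amplitude_rhs, classify_attractor, compute_coefficients, AmplitudeTrajectory,
    integrate_amplitudes, sustains_limit_cycle, _integrate_fast,
)


@pytest.fixture(scope="module")
def model59():
    return compute_coefficients(5.9)


@pytest.fixture(scope="module")
def model70():
    return compute_coefficients(7.0)


class TestCoefficients:
    def test_linear_rates_match_stability_module(self, model59):
        assert model59.lambda0 == pytest.approx(growth_rate(0, 5.9), abs=1e-6)
        assert model59.lambda1 == pytest.approx(growth_rate(1, 5.9), abs=1e-6)
        assert model59.lambda2 == pytest.approx(growth_rate(2, 5.9), abs=1e-6)

    def test_saturating_single_vortex_coupling(self, model59):
        # c1 > 0 is required for the bounded steady vortex at smaller radii
        assert np.real(model59.c1) > 0
        for name in ("c1", "c2", "c3", "c4", "b1", "b2", "b3", "b4",
                     "delta1", "gamma1", "a1", "a2", "a3", "a4", "delta2", "gamma2"):
            assert np.isfinite(getattr(model59, name))

    def test_hand_derived_quadrature_oracle(self, model59):
        # independently derived closed form for the A1^2 -> A2 advective
        # coupling: gamma2 = -i lam 2pi int psi2 (psi1 w1' + vth1 w1) dr / D2
        from vortexwell.linear_stability import eigenmode
        m1, m2 = eigenmode(1, 5.9), eigenmode(2, 5.9)
        wq, r = m1.quad_weights, m1.r
        D2 = 2 * np.pi * np.sum(wq * r * m2.psi * m2.omega)
        g2 = -1j * 9.0 * 2 * np.pi * np.sum(
            wq * m2.psi * (m1.psi * m1.d_omega + m1.v_theta * m1.omega)) / D2
        assert model59.gamma2 == pytest.approx(g2, abs=1e-10)

    def test_gauge_structure(self, model59):
        # real-profile gauge: cubic couplings real, advective couplings imaginary
        for name in ("c1", "c2", "c3", "b1", "b2", "b3", "a1", "a2", "a3"):
            assert abs(np.imag(getattr(model59, name))) < 1e-10
        for name in ("delta1", "gamma1", "delta2", "gamma2"):
            v = getattr(model59, name)
            assert abs(np.real(v)) < 1e-10 * max(1.0, abs(v))

    def test_lam_rescaling(self, model59):
        m2 = model59.with_lam(4.5)
        assert m2.gamma2 == pytest.approx(model59.gamma2 / 2.0)
        assert m2.c1 == model59.c1
        assert m2.lambda0 == model59.lambda0


class TestSymmetries:
    def test_rotation_equivariance_of_vector_field(self, model59):
        rng = np.random.default_rng(0)
        for _ in range(5):
            C = rng.standard_normal()
            A1 = rng.standard_normal() + 1j * rng.standard_normal()
            A2 = rng.standard_normal() + 1j * rng.standard_normal()
            phi = rng.uniform(0, 2 * np.pi)
            dC, dA1, dA2 = amplitude_rhs(model59, C, A1, A2)
            dCr, dA1r, dA2r = amplitude_rhs(
                model59, C, A1 * np.exp(1j * phi), A2 * np.exp(2j * phi))
            assert dCr == pytest.approx(dC, abs=1e-10)
            assert dA1r == pytest.approx(dA1 * np.exp(1j * phi), abs=1e-10)
            assert dA2r == pytest.approx(dA2 * np.exp(2j * phi), abs=1e-10)

    def test_parity_maps_trajectories(self, model59):
        # (C, A1, A2) -> (-C, -A1*, -A2*) is the vorticity sign flip behind
        # the CW/CCW symmetry of the reversal statistics
        rng = np.random.default_rng(1)
        for _ in range(5):
            C = rng.standard_normal()
            A1 = rng.standard_normal() + 1j * rng.standard_normal()
            A2 = rng.standard_normal() + 1j * rng.standard_normal()
            dC, dA1, dA2 = amplitude_rhs(model59, C, A1, A2)
            dCp, dA1p, dA2p = amplitude_rhs(model59, -C, -np.conj(A1), -np.conj(A2))
            assert dCp == pytest.approx(-dC, abs=1e-10)
            assert dA1p == pytest.approx(-np.conj(dA1), abs=1e-10)
            assert dA2p == pytest.approx(-np.conj(dA2), abs=1e-10)

    def test_packed_rhs_matches_reference(self, model59):
        from vortexwell.normal_form import _rhs_packed
        rng = np.random.default_rng(2)
        y = rng.standard_normal(5)
        d = _rhs_packed(y, model59.pack())
        dC, dA1, dA2 = amplitude_rhs(model59, y[0], y[1] + 1j * y[2], y[3] + 1j * y[4])
        assert d[0] == pytest.approx(dC, abs=1e-12)
        assert d[1] + 1j * d[2] == pytest.approx(dA1, abs=1e-12)
        assert d[3] + 1j * d[4] == pytest.approx(dA2, abs=1e-12)


class TestIntegration:
    def test_origin_is_fixed_point(self, model59):
        traj = integrate_amplitudes(model59, (0.0, 0.0, 0.0), 50.0, n_out=100)
        assert np.all(np.abs(traj.C) == 0)
        assert np.all(np.abs(traj.A1) == 0)

    def test_reversing_orbit_at_R59(self, model59):
        rng = np.random.default_rng(3)
        y0 = 1e-2 * rng.standard_normal(5)
        T, Y = _integrate_fast(model59, y0, t_end=4000.0)
        assert sustains_limit_cycle(T, Y) == "reversing"

    def test_pulsating_orbit_at_R70(self, model70):
        # C suppressed, |A1| and |A2| oscillate in antiphase
        rng = np.random.default_rng(4)
        y0 = 1e-2 * rng.standard_normal(5)
        T, Y = _integrate_fast(model70, y0, t_end=3000.0)
        assert sustains_limit_cycle(T, Y) == "pulsating"
        i0 = len(T) // 2
        A1 = np.abs(Y[i0:, 1] + 1j * Y[i0:, 2])
        A2 = np.abs(Y[i0:, 3] + 1j * Y[i0:, 4])
        assert np.mean(np.abs(Y[i0:, 0])) < 0.1 * np.mean(A1)
        assert np.corrcoef(A1, A2)[0, 1] < -0.3

    def test_truncation_honesty_near_first_onset(self):
        # where only the axisymmetric mode is unstable the C-only fixed
        # point sqrt(lambda0/c1) matches the full three-mode equilibrium
        m = compute_coefficients(4.5)
        c_star = np.sqrt(m.lambda0 / np.real(m.c1))
        T, Y = _integrate_fast(m, np.array([0.1, 1e-3, 0.0, 1e-3, 0.0]), t_end=2000.0)
        assert abs(Y[-1, 0]) == pytest.approx(c_star, rel=0.01)

    def test_blow_up_reported(self, model59):
        bad = model59.with_lam(9.0)
        bad.c1 = -abs(bad.c1)  # destabilize the cubic
        bad.b1 = -abs(np.real(bad.b1))
        bad.a1 = -abs(np.real(bad.a1))
        with pytest.raises(FloatingPointError):
            integrate_amplitudes(bad, (1.0, 0.1 + 0j, 0.1 + 0j), 500.0)


class TestClassification:
    def test_constant_trajectory_is_fixed_point(self):
        t = np.linspace(0, 100, 500)
        traj = AmplitudeTrajectory(times=t, C=np.full_like(t, 1.3),
                                   A1=np.full_like(t, 0.2, dtype=complex),
                                   A2=np.zeros_like(t, dtype=complex))
        label, period = classify_attractor(traj)
        assert label == "fixed_point" and period is None

    def test_synthetic_sine_period_recovered(self):
        P = 37.0
        t = np.linspace(0, 1000, 20000)
        traj = AmplitudeTrajectory(times=t, C=np.sin(2 * np.pi * t / P),
                                   A1=np.full_like(t, 0.5, dtype=complex),
                                   A2=np.zeros_like(t, dtype=complex))
        label, period = classify_attractor(traj)
        assert label == "reversing_cycle"
        assert period == pytest.approx(P, rel=0.01)

    def test_short_window_indeterminate(self):
        t = np.linspace(0, 4, 16)
        traj = AmplitudeTrajectory(times=t, C=0.5 + 0.3 * np.sin(0.1 * t),
                                   A1=np.zeros_like(t, dtype=complex),
                                   A2=np.zeros_like(t, dtype=complex))
        label, _ = classify_attractor(traj)
        assert label in ("indeterminate", "unclassified")
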