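"""Forward-model tests: cascade stages, closed form vs ODE, quadrature."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import nocifit as nf
from nocifit.model import (
    ModelConstants,
    Stimulus,
    initial_panels,
    membrane_response_kernel,
    pulse_onsets,
)


class TestPeripheralDrive:
    @pytest.mark.parametrize(
        "A, PW, tau1, expected",
        [
            (1.0, 0.42, 1e-12, 1.0),  # saturation: the membrane charges fully
            (0.0, 0.42, 0.1, 0.0),  # zero amplitude
            (1.0, 0.42, 0.1, -math.expm1(-4.2)),  # 1 - e^-4.2
        ],
    )
    def test_values(self, A, PW, tau1, expected):
        assert nf.peripheral_drive(A, PW, tau1) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("PW, tau1", [(0.0, 0.1), (-1.0, 0.1), (0.42, 0.0)])
    def test_domain_errors(self, PW, tau1):
        with pytest.raises(ValueError):
            nf.peripheral_drive(1.0, PW, tau1)

    @given(
        A=st.floats(0.0, 10.0),
        PW=st.floats(0.01, 5.0),
        tau1=st.floats(0.01, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_increasing_in_pw(self, A, PW, tau1):
        # fA < A mathematically; equality only when exp(-PW/tau1)
        # underflows double precision
        fA = nf.peripheral_drive(A, PW, tau1)
        assert 0.0 <= fA <= A
        assert nf.peripheral_drive(A, PW * 2, tau1) >= fA


class TestEffectiveActivation:
    @pytest.mark.parametrize(
        "fA, alpha1, expected",
        [(0.05, 0.1, 0.0), (0.1, 0.1, 0.0), (0.3, 0.1, 0.2)],
    )
    def test_threshold_linear(self, fA, alpha1, expected):
        assert nf.effective_activation(fA, alpha1) == pytest.approx(expected)


class TestMembranePotential:
    def test_causality(self, reference_theta, constants):
        stim = Stimulus(A=1.5, NoP=2, IPI=50.0, PW=0.42)
        t = np.array([-5.0, -1.0, 0.0])
        assert np.all(nf.membrane_potential(t, stim, reference_theta, constants) == 0.0)
        # second pulse contributes nothing before its onset at 50 ms
        single = Stimulus(A=1.5, NoP=1, PW=0.42)
        t = np.linspace(0.1, 49.9, 25)
        np.testing.assert_allclose(
            nf.membrane_potential(t, stim, reference_theta, constants),
            nf.membrane_potential(t, single, reference_theta, constants),
            rtol=1e-12,
        )

    def test_superposition(self, reference_theta, constants):
        """A two-pulse response is the sum of two shifted one-pulse responses."""
        stim = Stimulus(A=1.5, NoP=2, IPI=10.0, PW=0.42)
        single = Stimulus(A=1.5, NoP=1, PW=0.42)
        t = np.linspace(0.0, 200.0, 101)
        x2 = nf.membrane_potential(t, stim, reference_theta, constants)
        x1 = nf.membrane_potential(t, single, reference_theta, constants)
        x1_shift = nf.membrane_potential(t - 10.0, single, reference_theta, constants)
        np.testing.assert_allclose(x2, x1 + x1_shift, rtol=1e-12, atol=1e-300)

    def test_closed_form_vs_ode(self, random_params, constants):
        """Exact solution matches adaptive integration of the leaky
        integrator driven by the explicit synaptic current, to 1e-6 of the
        trajectory scale, across the feasible space."""
        rng = np.random.default_rng(1)
        checked = 0
        for theta in random_params:
            nop = int(rng.choice([1, 2]))
            ipi = None if nop == 1 else float(rng.choice([10.0, 50.0, 100.0]))
            stim = Stimulus(
                A=float(rng.uniform(0.5, 3.0)),
                NoP=nop,
                IPI=ipi,
                PW=float(rng.choice([0.42, 0.84])),
            )
            c = nf.effective_activation(
                nf.peripheral_drive(stim.A, stim.PW, theta.tau1), theta.alpha1
            )
            if c == 0.0:
                continue
            x_ode = _ode_oracle(stim, theta, constants, c, rng)
            t_pts, x_ref = x_ode
            x_closed = nf.membrane_potential(t_pts, stim, theta, constants)
            scale = np.max(np.abs(x_closed))
            assert np.max(np.abs(x_closed - x_ref)) <= 1e-6 * scale
            checked += 1
        assert checked >= 15

    def test_tau2_near_tau_s_limit(self, constants):
        """The two analytic branches agree across the removable singularity."""
        onsets = np.array([0.0])
        t = np.linspace(0.5, 20.0, 40)
        tau_s = constants.tau_s
        g_limit = membrane_response_kernel(t, onsets, tau_s, tau_s)
        g_near = membrane_response_kernel(t, onsets, tau_s * (1 + 1e-9), tau_s)
        np.testing.assert_allclose(g_near, g_limit, rtol=1e-6)
        # limit formula equals the analytic limit s*exp(-s/tau_s)/tau_s^2
        np.testing.assert_allclose(
            g_limit, t * np.exp(-t / tau_s) / tau_s**2, rtol=1e-12
        )


def _ode_oracle(stim, theta, constants, c, rng):
    onsets = list(pulse_onsets(stim))

    def rhs(t, x):
        drive = sum(
            math.exp(-(t - tk) / constants.tau_s) for tk in onsets if t >= tk
        )
        return [(-x[0] + c * drive / constants.tau_s) / theta.tau2]

    t_pts = np.sort(rng.uniform(0.1, 300.0, 20))
    edges = sorted(set(onsets + list(t_pts) + [300.0]))
    values = {}
    x0, t_prev = 0.0, 0.0
    for edge in edges:
        if edge <= t_prev:
            continue
        sol = solve_ivp(rhs, (t_prev, edge), [x0], rtol=1e-12, atol=1e-18)
        x0, t_prev = float(sol.y[0, -1]), edge
        values[edge] = x0
    return t_pts, np.array([values[t] for t in t_pts])


class TestFiringRate:
    def test_midpoint_and_saturation(self, reference_theta):
        theta = reference_theta
        assert nf.firing_rate(theta.alphaL, theta) == pytest.approx(theta.lambdaL / 2)
        assert nf.firing_rate(1e6, theta) == pytest.approx(theta.lambdaL)

    def test_resting_rate_reference(self, reference_theta):
        """At x = 0 the rate is lambdaL / (1 + exp(alphaL / sigmaL))."""
        expected = 0.4020 / (1.0 + math.exp(0.022 / 0.0021))
        assert nf.firing_rate(0.0, reference_theta) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.13e-5, rel=0.01)

    def test_no_overflow(self, reference_theta):
        theta = reference_theta.replace(sigmaL=1e-8)
        for x in (-1e9, 0.0, 1e9):
            rate = nf.firing_rate(x, theta)
            assert np.isfinite(rate) and 0.0 <= rate <= theta.lambdaL

    def test_strictly_increasing(self, reference_theta):
        x = np.linspace(0.0, 0.05, 200)
        rates = nf.firing_rate(x, reference_theta)
        assert np.all(np.diff(rates) > 0)


class TestDetectionProbability:
    def test_quadrature_vs_trapezoid(self, reference_theta, constants):
        """Adaptive quadrature matches a dense (1e5-node) trapezoid oracle."""
        stimuli = [
            Stimulus(A=1.2, NoP=1, PW=0.42),
            Stimulus(A=1.0, NoP=2, IPI=10.0, PW=0.42),
            Stimulus(A=2.5, NoP=2, IPI=100.0, PW=0.84),
            Stimulus(A=0.8, NoP=1, PW=0.84),
        ]
        for stim in stimuli:
            lam = nf.expected_spike_count(stim, reference_theta, constants)
            t = np.linspace(0.0, constants.T, 100001)
            x = nf.membrane_potential(t, stim, reference_theta, constants)
            lam_trap = np.trapezoid(nf.firing_rate(x, reference_theta), t)
            assert abs(lam - lam_trap) <= 1e-6

    def test_monotone_in_amplitude(self, reference_theta, constants):
        amps = [0.2, 0.6, 1.0, 1.4, 2.0, 2.8]
        psis = [
            nf.detection_probability(Stimulus(A=a, PW=0.42), reference_theta, constants)
            for a in amps
        ]
        assert all(0.0 <= p < 1.0 for p in psis)
        assert np.all(np.diff(psis) >= 0)
        assert psis[-1] >= psis[0]

    def test_monotone_in_thresholds(self, reference_theta, constants):
        """Raising either threshold can only lower the detection probability."""
        stim = Stimulus(A=1.3, PW=0.42)
        base = nf.detection_probability(stim, reference_theta, constants)
        for name in ("alpha1", "alphaL"):
            raised = reference_theta.replace(**{name: getattr(reference_theta, name) * 1.2})
            lowered = reference_theta.replace(**{name: getattr(reference_theta, name) * 0.8})
            assert nf.detection_probability(stim, raised, constants) <= base
            assert nf.detection_probability(stim, lowered, constants) >= base

    def test_vanishing_rate(self, reference_theta, constants):
        theta = reference_theta.replace(lambdaL=1e-12)
        psi = nf.detection_probability(Stimulus(A=2.0, PW=0.42), theta, constants)
        assert psi == pytest.approx(0.0, abs=1e-8)

    def test_fast_path_matches_adaptive(self, ts1_dataset, reference_theta, constants):
        """The cached fixed-grid likelihood quadrature agrees with the
        adaptive public evaluation at data-relevant parameters."""
        evaluator = nf.LikelihoodEvaluator(ts1_dataset, constants)
        psi_fast = evaluator.psi(reference_theta)
        for (label, amp), p_fast in list(psi_fast.items())[::7]:
            nop, ipi, pw = ts1_dataset.combos[label]
            stim = Stimulus(A=amp, NoP=nop, IPI=ipi, PW=pw, combo_label=label)
            p_exact = nf.detection_probability(stim, reference_theta, constants)
            assert p_fast == pytest.approx(p_exact, abs=1e-7)


class TestValidation:
    def test_stimulus_invariants(self):
        with pytest.raises(ValueError):
            Stimulus(A=1.0, NoP=2, IPI=None, PW=0.42)
        with pytest.raises(ValueError):
            Stimulus(A=1.0, NoP=1, IPI=10.0, PW=0.42)
        with pytest.raises(ValueError):
            Stimulus(A=-1.0, PW=0.42)
        with pytest.raises(ValueError):
            Stimulus(A=1.0, PW=0.0)

    def test_short_trial_window_warns(self, reference_theta):
        constants = ModelConstants(T=100.0)
        stim = Stimulus(A=1.0, NoP=2, IPI=50.0, PW=0.42)
        with pytest.warns(UserWarning, match="truncated"):
            constants.validate_for(stim, reference_theta)

    def test_params_positive(self):
        with pytest.raises(ValueError):
            nf.HazardParams(0.0, 0.1, 50.0, 0.022, 0.0021, 0.402)

    def test_initial_panels_cover_trial_window(self, constants):
        stim = Stimulus(A=1.0, NoP=2, IPI=50.0, PW=0.42)
        panels = initial_panels(stim, constants)
        assert panels[0][0] == 0.0
        assert panels[-1][1] == constants.T
        for (a0, b0), (a1, _) in zip(panels[:-1], panels[1:]):
            assert b0 == a1 and b0 > a0
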