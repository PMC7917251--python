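"""Forward-simulation correctness: closed forms, oracles, clamp identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import minmod as mm
from minmod.errors import ConvergenceError, InputDomainError, ParameterError


def euler_oracle(params, insulin, t_eval, dt=1e-3):
    """Independent fixed-step Euler integration of the two model equations."""
    t_eval = np.asarray(t_eval, dtype=float)
    g, x = params.G0, 0.0
    out_g, out_x = [g], [x]
    t = t_eval[0]
    for t1 in t_eval[1:]:
        n = int(round((t1 - t) / dt))
        h = (t1 - t) / n
        for i in range(n):
            di = float(insulin(t + i * h)) - params.Ib
            dg = -(params.p1 + x) * g + params.p1 * params.Gb
            dx = -params.p2 * x + params.p3 * di
            g += h * dg
            x += h * dx
        t = t1
        out_g.append(g)
        out_x.append(x)
    return np.array(out_g), np.array(out_x)


class TestSimulate:
    def test_equilibrium_fixed_point(self, normal_params):
        """G0=Gb with basal insulin forever leaves the system at rest."""
        p = normal_params.replace(G0=normal_params.Gb)
        insulin = mm.InsulinInput.constant(p.Ib, (-10, 200))
        traj = mm.simulate_minimal_model(p, insulin, np.arange(0.0, 181.0))
        assert np.allclose(traj.glucose, p.Gb, rtol=1e-9)
        assert np.allclose(traj.remote_insulin, 0.0, atol=1e-12)

    @pytest.mark.parametrize("method", ["rk4", "lsoda"])
    def test_monoexponential_when_no_insulin_action(self, normal_params, template_input, method):
        """p3=0 decouples glucose from insulin: exact first-order decay to Gb."""
        p = normal_params.replace(p3=0.0)
        t = np.arange(0.0, 181.0)
        traj = mm.simulate_minimal_model(p, template_input, t, method=method)
        exact = p.Gb + (p.G0 - p.Gb) * np.exp(-p.p1 * t)
        assert np.max(np.abs(traj.glucose - exact) / exact) <= 1e-6

    def test_against_fine_step_euler_oracle(self, template_input):
        """Production integrator vs brute-force fine-step Euler.

        A 5e-4 min step keeps the first-order oracle's own bias below the
        1e-5 comparison band (at 1e-3 min it is ~1.1e-5 on this trajectory,
        i.e. the oracle, not the solver, dominates the difference).
        """
        p = mm.MinimalModelParams(p1=0.02, p2=0.03, p3=1.5e-5, Gb=90, Ib=10, G0=280)
        t_eval = np.arange(0.0, 61.0, 5.0)
        g_ref, x_ref = euler_oracle(p, template_input, t_eval, dt=5e-4)
        traj = mm.simulate_minimal_model(p, template_input, t_eval)
        assert np.max(np.abs(traj.glucose - g_ref) / g_ref) <= 1e-5

    def test_rk4_and_lsoda_agree(self, normal_params, template_input):
        t = np.arange(0.0, 181.0)
        a = mm.simulate_minimal_model(normal_params, template_input, t, method="rk4")
        b = mm.simulate_minimal_model(normal_params, template_input, t, method="lsoda")
        assert np.max(np.abs(a.glucose - b.glucose) / b.glucose) <= 1e-6

    @given(extra=st.floats(min_value=1.0, max_value=100.0))
    def test_more_insulin_lowers_glucose_pointwise(self, normal_params, extra):
        """A pointwise-larger insulin input can only depress the trajectory."""
        t_nodes = np.arange(-10.0, 181.0)
        tpl = mm.InsulinCurveTemplate()
        base = np.asarray(tpl(t_nodes))
        lo = mm.InsulinInput(t_nodes, base)
        hi = mm.InsulinInput(t_nodes, base + np.where(t_nodes > 0, extra, 0.0))
        t = np.arange(0.0, 181.0)
        g_lo = mm.simulate_minimal_model(normal_params, lo, t).glucose
        g_hi = mm.simulate_minimal_model(normal_params, hi, t).glucose
        assert np.all(g_hi <= g_lo + 1e-9)

    def test_insulin_coverage_gap_rejected(self, normal_params):
        insulin = mm.InsulinInput.constant(10.0, (0.0, 100.0))
        with pytest.raises(InputDomainError):
            mm.simulate_minimal_model(normal_params, insulin, np.arange(0.0, 181.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            mm.MinimalModelParams(p1=0.02, p2=0.0, p3=1e-5, Gb=90, Ib=10, G0=280)
        with pytest.raises(ParameterError):
            mm.MinimalModelParams(p1=-0.01, p2=0.03, p3=1e-5, Gb=90, Ib=10, G0=280)


class TestSteadyStateRemoteInsulin:
    def test_zero_increment(self, normal_params):
        assert mm.steady_state_remote_insulin(normal_params, normal_params.Ib) == 0.0

    def test_unit_increment_equals_si(self, normal_params):
        x = mm.steady_state_remote_insulin(normal_params, normal_params.Ib + 1.0)
        assert x == pytest.approx(normal_params.SI, rel=1e-12)

    def test_signed_vs_clipped_below_basal(self, normal_params):
        level = normal_params.Ib - 5.0
        assert mm.steady_state_remote_insulin(normal_params, level) < 0
        assert mm.steady_state_remote_insulin(normal_params, level, clip=True) == 0.0

    def test_long_simulation_converges_to_steady_state(self, normal_params):
        """X under constant insulin approaches (p3/p2) * dI within 1e-8 by 500 min."""
        step = 50.0
        insulin = mm.InsulinInput.constant(normal_params.Ib + step, (-10, 600))
        traj = mm.simulate_minimal_model(
            normal_params.replace(G0=normal_params.Gb), insulin, np.array([0.0, 500.0])
        )
        x_ss = mm.steady_state_remote_insulin(normal_params, normal_params.Ib + step)
        assert abs(traj.remote_insulin[-1] - x_ss) <= 1e-8


class TestClamp:
    def test_zero_step_gives_zero_disposal(self, normal_params):
        res = mm.simulate_clamp(normal_params, 0.0, duration=400.0)
        assert res.delta_rd == 0.0

    @given(
        p2=st.floats(min_value=0.01, max_value=0.3),
        si=st.floats(min_value=1e-4, max_value=1e-3),
        step=st.floats(min_value=5.0, max_value=200.0),
    )
    def test_steady_state_sensitivity_equals_si(self, p2, si, step):
        """Clamp identity: Delta-Rd/(Delta-I * G * VD) = p3/p2 at steady state."""
        p = mm.MinimalModelParams(p1=0.02, p2=p2, p3=si * p2, Gb=90, Ib=10, G0=90, VD=1.8)
        res = mm.simulate_clamp(p, step, duration=16.0 / p2)
        assert res.sensitivity == pytest.approx(p.SI, rel=1e-6)
        assert res.sensitivity_volume_scaled == pytest.approx(p.SI * 1.8, rel=1e-6)

    def test_finite_clamp_transient_factor(self, normal_params):
        """A 180-min clamp at p2=0.03 sits below the asymptote by 1 - e^(-p2 t)."""
        res = mm.simulate_clamp(normal_params, 50.0, duration=180.0, require_converged=False)
        factor = 1.0 - np.exp(-normal_params.p2 * 180.0)
        assert not res.converged
        assert res.sensitivity / normal_params.SI == pytest.approx(factor, rel=1e-6)

    def test_unconverged_clamp_reports_achieved_fraction(self, normal_params):
        with pytest.raises(ConvergenceError) as exc:
            mm.simulate_clamp(normal_params, 50.0, duration=60.0)
        assert 0 < exc.value.achieved < 0.999
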