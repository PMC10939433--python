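"""Compartmental discretisation: steady profiles, Jacobian, limits, kernels."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dendrosoma import _kernels
from dendrosoma.dendrite import DendriteSpec
from dendrosoma.system import DSSystem, ds_system
from dendrosoma import dynamics as dyn


def _settle_passive(system, I_ext, t_end=3000.0):
    sol = solve_ivp(lambda t, y: system.rhs(t, y, I_ext), (0.0, t_end),
                    system.initial_state(), method="LSODA",
                    rtol=1e-11, atol=1e-11)
    return sol.y[:, -1]


class TestSteadyState:
    def test_profile_matches_closed_form(self, passive_soma):
        # cash out the steady cable profile against cosh((ell - x)/1)/cosh(ell)
        dend = DendriteSpec.from_G_in(5.0, 2.0, tau_delta=10.0, ell=1.5)
        system = DSSystem(passive_soma, dend, M=50)
        y = _settle_passive(system, 20.0)
        prof = system.equilibrium_profile(y[0])
        rel = np.abs((y[1:] - prof) / (prof - passive_soma.E_L))
        assert rel.max() < 0.005

    def test_leak_only_input_conductance(self, passive_soma):
        # steady-state somatic voltage is E_L + I/G_in for any geometry
        for ell, td in [(1.5, 10.0), (None, 5.0), (0.7, 20.0)]:
            dend = DendriteSpec.from_G_in(4.0, 2.0, tau_delta=td, ell=ell)
            system = DSSystem(passive_soma, dend, M=50)
            y = _settle_passive(system, 12.0)
            expected = passive_soma.E_L + 12.0 / 4.0
            assert y[0] == pytest.approx(expected, abs=0.02)

    def test_grid_refinement_converges(self, passive_soma):
        # the discrete DC conductance approaches the analytic G_in as M grows,
        # so the steady somatic voltage moves by < 0.1% between M=50 and M=200
        dend = DendriteSpec.from_G_in(4.0, 2.0, tau_delta=10.0, ell=1.5)
        v = {}
        for M in (50, 200):
            system = DSSystem(passive_soma, dend, M=M)
            g = system.G_in_discrete()
            v[M] = passive_soma.E_L + 20.0 / g
        assert abs(v[50] - v[200]) / abs(v[200]) < 1e-3


class TestJacobian:
    @pytest.mark.parametrize("G_in,td,ell,M", [(4.0, 10.0, None, 20),
                                               (5.0, 2.5, 1.2, 35),
                                               (3.0, 0.0, None, 10)])
    def test_matches_finite_differences(self, G_in, td, ell, M, rng):
        system = ds_system(G_in, td, ell=ell, M=M)
        y = system.initial_state(-48.0) + rng.normal(0.0, 0.4, system.n_state)
        y[1] = float(np.clip(y[1], 0.05, 0.95))
        J = system.jacobian(y, 25.0)
        Jfd = np.empty_like(J)
        h = 1e-6
        for j in range(system.n_state):
            e = np.zeros(system.n_state)
            e[j] = h
            Jfd[:, j] = (system.rhs(0, y + e, 25.0) - system.rhs(0, y - e, 25.0)) / (2 * h)
        scale = np.abs(J).max()
        assert np.abs(J - Jfd).max() / scale < 1e-6


class TestInstantaneousCableLimit:
    def test_reduces_to_point_neuron(self, ml_soma):
        # tau_delta = 0: the DS right-hand side equals the point model with
        # the lumped leak G_L = G_in
        system = ds_system(4.5, 0.0)
        assert system.n_state == 2
        v, w = -35.0, 0.2
        got = system.rhs(0.0, np.array([v, w]), 40.0)[0]
        extra = (system.G_in - ml_soma.G_sigma) * (ml_soma.E_L - v)
        expected = ml_soma.f_S(v, [w], 40.0) + extra / ml_soma.C_sigma
        assert got == pytest.approx(expected, rel=1e-12)

    def test_kernel_trace_matches_point_model_ode(self, ml_soma):
        # the compiled integrator at tau_delta = 0 reproduces an independent
        # adaptive integration of the 2-dimensional point model
        system = ds_system(3.0, 0.0)
        I = 75.0
        tr = dyn.integrate(system, I, 400.0, record_dt=1.0)
        G_extra = system.G_in - ml_soma.G_sigma

        def rhs(t, y):
            dv = ml_soma.f_S(y[0], y[1:], I) + G_extra * (ml_soma.E_L - y[0]) / ml_soma.C_sigma
            ainf = ml_soma.gate_steady_states(y[0])
            tau = ml_soma.gate_time_constants(y[0])
            return [dv, (ainf[0] - y[1]) / tau[0]]

        sol = solve_ivp(rhs, (0, 400.0), system.initial_state(),
                        t_eval=tr.t, rtol=1e-10, atol=1e-10)
        # compare up to the first spike (trajectories decorrelate at spikes)
        pre = tr.t < (tr.spikes.times[0] - 5.0 if tr.spikes.n else 400.0)
        assert np.allclose(tr.v_sigma[pre], sol.y[0][pre], atol=0.05)


def test_kernel_step_equals_reference_rk4(ml_soma, rng):
    """One compiled RK4 step reproduces the same step built from system.rhs."""
    system = ds_system(4.2, 7.5, M=12)
    y0 = system.initial_state(-50.0) + rng.normal(0.0, 0.3, system.n_state)
    y0[1] = float(np.clip(y0[1], 0.0, 1.0))
    dt, I = 0.02, 33.0
    p = dyn._pack(system)
    sp, n, y_end, _ = _kernels.run_single(y0, p, I, dt * 0.99, dt, 0.0,
                                          -1.0, 0.0, 0, 10)
    f = lambda y: system.rhs(0.0, y, I)
    k1 = f(y0); k2 = f(y0 + dt / 2 * k1); k3 = f(y0 + dt / 2 * k2); k4 = f(y0 + dt * k3)
    ref = y0 + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    assert np.allclose(y_end, ref, rtol=1e-12, atol=1e-12)


def test_discretise_returns_consistent_pair(ml_soma):
    from dendrosoma.system import discretise

    system = ds_system(4.0, 5.0, M=8)
    rhs, jac = discretise(system)
    y = system.initial_state()
    assert rhs(0.0, y, 10.0).shape == (system.n_state,)
    assert jac(y, 10.0).shape == (system.n_state, system.n_state)
    with pytest.raises(ValueError):
        DSSystem(ml_soma, DendriteSpec(1.0, 1.0, ell=1.0), M=0)
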