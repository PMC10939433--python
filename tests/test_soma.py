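"""Somatic model: currents, gating curves, and biophysical cable parameters."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrosoma.dendrite import dendrite_from_biophysics
from dendrosoma.soma import morris_lecar_soma, soma_rhs


class TestSomaRHS:
    def test_leak_only_equilibrium(self, passive_soma):
        assert soma_rhs(passive_soma, passive_soma.E_L, []) == 0.0

    def test_input_conductance_relation(self, passive_soma):
        # a constant current G_sigma * dv drives the leak-only soma toward
        # E_L + dv: at v = E_L the initial slope is I/C, at v = E_L + dv it is 0
        dv = 7.0
        I = passive_soma.G_sigma * dv
        assert soma_rhs(passive_soma, passive_soma.E_L, [], I) == pytest.approx(
            I / passive_soma.C_sigma)
        assert soma_rhs(passive_soma, passive_soma.E_L + dv, [], I) == pytest.approx(0.0)

    def test_matches_finite_difference_of_current_sum(self, ml_soma):
        # d(f_S)/dv at steady gating agrees with a numerical derivative of the
        # assembled current sum (independent oracle for the analytic partials)
        for v in (-60.0, -40.0, -20.0, 0.0):
            df_dv, df_da, dainf, tau = ml_soma.partials_at_steady(v)
            a = ml_soma.gate_steady_states(v)
            h = 1e-5
            fd_v = (ml_soma.f_S(v + h, a) - ml_soma.f_S(v - h, a)) / (2 * h)
            assert df_dv == pytest.approx(fd_v, rel=1e-6)
            fd_a = (ml_soma.f_S(v, a + h) - ml_soma.f_S(v, a - h)) / (2 * h)
            assert df_da[0] == pytest.approx(fd_a, rel=1e-6)

    def test_rejects_bad_state(self, ml_soma):
        with pytest.raises(ValueError, match="non-finite"):
            soma_rhs(ml_soma, np.nan, [0.1])
        with pytest.raises(ValueError, match="'w'"):
            soma_rhs(ml_soma, -60.0, [1.5])

    def test_active_current_derivative_oracle(self, ml_soma):
        for v in np.linspace(-75, 15, 7):
            h = 1e-4
            fd = (ml_soma.i_active_inf(v + h) - ml_soma.i_active_inf(v - h)) / (2 * h)
            assert ml_soma.di_active_inf_dv(v) == pytest.approx(fd, rel=1e-5, abs=1e-8)


@settings(deadline=None, max_examples=50)
@given(v=st.floats(min_value=-200.0, max_value=200.0))
def test_gating_curves_bounded_and_tau_positive(v):
    soma = morris_lecar_soma()
    for g in [gate for cur in soma.currents for gate in cur.gates]:
        a = g.inf(v)
        assert 0.0 <= a <= 1.0
        if not g.instantaneous:
            assert g.tau(v) > 0.0


def test_gating_curves_saturate():
    soma = morris_lecar_soma()
    for g in [gate for cur in soma.currents for gate in cur.gates]:
        assert g.inf(-500.0) == pytest.approx(0.0, abs=1e-9)
        assert g.inf(500.0) == pytest.approx(1.0, abs=1e-9)


class TestBiophysicalCable:
    BASE = dict(c_delta=1.0, g_delta=0.4, r_a=150.0, d=2.0, L=None, G_sigma=2.0)

    def test_tau_is_capacitance_over_conductance(self):
        spec = dendrite_from_biophysics(**{**self.BASE, "c_delta": 0.4})
        assert spec.tau_delta == pytest.approx(1.0)

    def test_doubling_diameter_raises_conductance_not_tau(self):
        s1 = dendrite_from_biophysics(**self.BASE)
        s2 = dendrite_from_biophysics(**{**self.BASE, "d": 4.0})
        assert s2.tau_delta == s1.tau_delta
        # semi-infinite dendritic conductance scales as d^{3/2}
        g1 = s1.G_delta(self.BASE["G_sigma"])
        g2 = s2.G_delta(self.BASE["G_sigma"])
        assert g2 / g1 == pytest.approx(2.0 ** 1.5, rel=1e-12)
        assert g2 > g1

    def test_raising_leak_density_lowers_tau_raises_conductance(self):
        s1 = dendrite_from_biophysics(**self.BASE)
        s2 = dendrite_from_biophysics(**{**self.BASE, "g_delta": 0.8})
        assert s2.tau_delta < s1.tau_delta
        assert s2.G_delta(2.0) > s1.G_delta(2.0)

    def test_lambda_formula(self):
        spec = dendrite_from_biophysics(**self.BASE)
        lam_cm = math.sqrt(2.0e-4 / (4.0 * 150.0 * 0.4e-3))
        assert spec.lambda_ == pytest.approx(lam_cm * 1e4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dendrite_from_biophysics(**{**self.BASE, "g_delta": 0.0})
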