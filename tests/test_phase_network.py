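"""Coupling functions, phase locking, and the synchrony measure."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrosoma import phase_network as pn
from dendrosoma.dynamics import PRCurve, standard_phase_grid

GRID = standard_phase_grid()


def _prc(values):
    return PRCurve(GRID, np.asarray(values, dtype=float), 1.0, 0.0, 100.0)


class TestCouplingFromPRC:
    def test_even_prc_gives_null_coupling(self):
        H = pn.coupling_from_prc(_prc(1 - np.cos(2 * np.pi * GRID)))
        assert np.max(np.abs(H.H)) < 1e-9

    def test_odd_prc_doubles(self):
        H = pn.coupling_from_prc(_prc(np.sin(2 * np.pi * GRID)))
        np.testing.assert_allclose(H.H, 2 * np.sin(2 * np.pi * GRID), atol=1e-2)

    def test_oddness_identity_on_grid(self):
        rng = np.random.default_rng(0)
        coeffs = rng.normal(size=4)
        vals = sum(c * np.sin(2 * np.pi * (k + 1) * GRID) + abs(c) *
                   np.cos(2 * np.pi * (k + 1) * GRID) for k, c in enumerate(coeffs))
        H = pn.coupling_from_prc(_prc(vals))
        # H(psi) + H(1 - psi) = 0 at every grid point
        total = H(GRID) + H(1.0 - GRID)
        assert np.max(np.abs(total)) < 1e-8

    def test_half_cycle_zero(self):
        H = pn.coupling_from_prc(_prc(np.exp(-GRID / 0.3)))
        assert H(0.5) == pytest.approx(0.0, abs=1e-12)


class TestPhaseLockedStates:
    def test_sine_coupling_roots_and_stability(self):
        H = pn.coupling_from_prc(_prc(0.5 * np.sin(2 * np.pi * GRID)))  # H = sin
        locks = pn.phase_locked_states(H)
        # H = sin(2 pi psi): H' > 0 at 0 (unstable), H' < 0 at 1/2 (stable)
        stable = {round(p, 3): s for p, s in locks}
        assert stable.get(0.5) is True
        assert stable.get(0.0) is False

    def test_detuning_shifts_roots(self):
        H = pn.coupling_from_prc(_prc(0.5 * np.sin(2 * np.pi * GRID)))
        locks = pn.phase_locked_states(H, delta_omega=0.3)
        roots = sorted(p for p, _ in locks)
        assert all(abs(pn_val := 0.3 + float(H(r))) < 1e-8 for r in roots)


class TestSimulatePhaseODE:
    def test_converges_to_stable_root(self):
        H = pn.coupling_from_prc(_prc(0.5 * np.sin(2 * np.pi * GRID)))
        t, psi = pn.simulate_phase_ode(H, 0.0, 0.3, 50.0)
        assert psi[-1] == pytest.approx(0.5, abs=1e-3)

    def test_fixed_point_stays_fixed(self):
        H = pn.coupling_from_prc(_prc(0.5 * np.sin(2 * np.pi * GRID)))
        t, psi = pn.simulate_phase_ode(H, 0.0, 0.5, 20.0)
        assert np.max(np.abs(psi - 0.5)) < 1e-9

    def test_weaker_coupling_converges_more_slowly(self):
        strong = pn.coupling_from_prc(_prc(0.5 * np.sin(2 * np.pi * GRID)))
        weak = pn.coupling_from_prc(_prc(0.05 * np.sin(2 * np.pi * GRID)))
        def t_half(H):
            t, psi = pn.simulate_phase_ode(H, 0.0, 0.26, 400.0, dt=0.01)
            idx = np.argmax(np.abs(psi - 0.5) < 0.01)
            return t[idx] if idx else np.inf
        assert t_half(weak) > 5 * t_half(strong)


class TestSynchronyMeasure:
    def test_in_phase_is_one(self):
        for n in range(2, 11):
            psis = np.zeros(n)
            psis[0] = 1.0
            assert pn.synchrony_R(psis) == pytest.approx(1.0, abs=1e-12)

    def test_splay_is_zero(self):
        for n in range(2, 11):
            assert pn.synchrony_R(np.full(n, 1.0 / n)) == pytest.approx(0.0, abs=1e-12)

    def test_two_neuron_worked_value(self):
        # psi = (0.75, 0.25): R = sqrt(2 (0.625 - 0.5)) = 0.5 exactly
        assert pn.synchrony_R([0.75, 0.25]) == pytest.approx(0.5, abs=1e-12)

    def test_sum_violation_raises(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pn.synchrony_R([0.5, 0.6])

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=8),
           st.randoms())
    def test_bounded_and_permutation_invariant(self, raw, pyrandom):
        psis = np.asarray(raw) / np.sum(raw)
        r = pn.synchrony_R(psis)
        assert 0.0 <= r <= 1.0 + 1e-12
        perm = list(range(len(psis)))
        pyrandom.shuffle(perm)
        assert pn.synchrony_R(psis[perm]) == pytest.approx(r, abs=1e-12)

    def test_phase_gaps_sum_to_one(self):
        gaps = pn.phase_gaps([0.9, 0.1, 0.45])
        assert gaps.sum() == pytest.approx(1.0)
        assert np.all(gaps >= 0)


def test_uncoupled_network_preserves_phase_offsets(ml_soma):
    """Phase extraction sanity: with zero coupling the configuration drifts
    by less than 0.02 cycles over 20 periods."""
    from dendrosoma.system import ds_system
    from dendrosoma import dynamics as dyn

    system = ds_system(3.0, 0.0)
    on = dyn.onset_current(system, rate_target=4.0, transient=1000,
                           window=2500, min_spikes=6, tol=0.05)
    y0, period = dyn.limit_cycle_state(system, on.I_ext)
    res = pn.simulate_compartmental_network(system, 2, on.I_ext, 0.0,
                                            20 * period, [0.0, 0.3])
    d = res.psi[:, 0]
    d = np.minimum(d, 1 - d)
    assert abs(d[-1] - 0.3) < 0.02
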