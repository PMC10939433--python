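"""Fixed points and local bifurcations of the soma-plus-cable system."""
import numpy as np
import pytest

from dendrosoma import bifurcation as bif
from dendrosoma.system import ds_system


class TestFixedPoints:
    def test_leak_only_steady_current(self, passive_soma):
        v = np.array([-70.0, -55.0, -40.0])
        got = bif.steady_state_current(passive_soma, v, G_in=4.0)
        np.testing.assert_allclose(got, 4.0 * (-60.0 - v))

    def test_fixed_point_count_switches_between_saddle_nodes(self, ml_soma):
        # three equilibria strictly between the SN currents, one outside
        sn_lo, sn_hi = bif.find_saddle_nodes(ml_soma, 4.0)
        mid = 0.5 * (sn_lo.I_ext + sn_hi.I_ext)
        assert len(bif.find_fixed_points(ml_soma, mid, G_in=4.0, classify=False)) == 3
        assert len(bif.find_fixed_points(ml_soma, sn_lo.I_ext - 10.0, G_in=4.0,
                                         classify=False)) == 1
        assert len(bif.find_fixed_points(ml_soma, sn_hi.I_ext + 10.0, G_in=4.0,
                                         classify=False)) == 1

    def test_stability_labels(self, ml_soma):
        system = ds_system(4.0, 5.0, M=30)
        sn_lo, sn_hi = bif.find_saddle_nodes(ml_soma, 4.0)
        fps = bif.find_fixed_points(system, 0.5 * (sn_lo.I_ext + sn_hi.I_ext))
        assert [fp.stable for fp in fps].count(True) == 1  # rest state only


class TestSaddleNodesAndCusp:
    def test_sn_bracket_matches_root_count_oracle(self, ml_soma):
        # brute-force root counting on a dense voltage grid brackets the same
        # three-fixed-point current interval as the analytic SN conditions
        G = 4.5
        sn_lo, sn_hi = bif.find_saddle_nodes(ml_soma, G)
        vs = np.linspace(-80, 20, 40001)

        def n_roots(I):
            f = bif.steady_state_current(ml_soma, vs, G_in=G) + I
            return int(np.sum(np.sign(f[:-1]) != np.sign(f[1:])))

        eps = 0.05
        assert n_roots(sn_lo.I_ext + eps) == 3
        assert n_roots(sn_hi.I_ext - eps) == 3
        assert n_roots(sn_lo.I_ext - eps) == 1
        assert n_roots(sn_hi.I_ext + eps) == 1

    def test_no_pair_above_cusp(self, ml_soma):
        cusp = bif.find_cusp(ml_soma)
        with pytest.raises(ValueError, match="cusp"):
            bif.find_saddle_nodes(ml_soma, cusp.G_in + 0.05)

    def test_sn_branches_merge_at_cusp(self, ml_soma):
        # continuation oracle: the SN pair collapses onto the cusp voltage as
        # G_in approaches the cusp conductance from below
        cusp = bif.find_cusp(ml_soma)
        gap_far = np.diff([p.v_sigma for p in bif.find_saddle_nodes(ml_soma, cusp.G_in - 0.5)])
        gap_near = np.diff([p.v_sigma for p in bif.find_saddle_nodes(ml_soma, cusp.G_in - 1e-4)])
        assert abs(gap_near) < 0.05 * abs(gap_far)
        mid = np.mean([p.v_sigma for p in bif.find_saddle_nodes(ml_soma, cusp.G_in - 1e-4)])
        assert mid == pytest.approx(cusp.v_sigma, abs=0.05)


class TestCharacteristicFunction:
    @pytest.mark.parametrize("ell", [None, 5.0, 1.2])
    def test_chi_zero_is_saddle_node_condition(self, ml_soma, ell):
        # chi(0) = 0 iff dI_inf/dv = 0, for arbitrary voltage draws
        for v in np.linspace(-70, 0, 9):
            for td in (0.0, 4.0, 18.0):
                G = 4.4
                chi = bif.CharacteristicFunction(ml_soma, G, td, ell)
                dIdv = ml_soma.di_active_inf_dv(v) - G
                assert complex(chi(0.0, v)).real == pytest.approx(
                    -dIdv / ml_soma.C_sigma, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("ell", [None, 5.0, 1.2])
    def test_dchi_ds0_matches_numerical_derivative(self, ml_soma, ell):
        # the closed-form s-derivative at 0 (the BT equation ingredient)
        # agrees with a central difference of chi along the real axis
        for v, td in [(-30.0, 7.0), (-15.0, 0.5), (-45.0, 20.0)]:
            chi = bif.CharacteristicFunction(ml_soma, 4.8, td, ell)
            h = 1e-6
            fd = (complex(chi(h, v)) - complex(chi(-h, v))).real / (2 * h)
            assert chi.dchi_ds0(v) == pytest.approx(fd, rel=1e-6)

    def test_alpha0_semi_infinite_is_half(self, ml_soma):
        chi = bif.CharacteristicFunction(ml_soma, 4.0, 10.0, None)
        assert chi.alpha0 == 0.5
        chi_long = bif.CharacteristicFunction(ml_soma, 4.0, 10.0, 20.0)
        assert chi_long.alpha0 == pytest.approx(0.5, abs=1e-6)


class TestBTandBTC:
    def test_bt_moves_to_higher_conductance_below_btc(self, ml_soma):
        btc = bif.find_btc(ml_soma)
        g = [bif.find_bt(ml_soma, td).G_in for td in (0.0, 4.0, 8.0, 12.0)]
        assert all(td < btc.tau_delta for td in (0.0, 4.0, 8.0, 12.0))
        assert np.all(np.diff(g) > 0)

    def test_bt_decreases_beyond_btc(self, ml_soma):
        btc = bif.find_btc(ml_soma)
        g_hi = [bif.find_bt(ml_soma, td).G_in for td in (15.0, 20.0)]
        assert g_hi[1] < g_hi[0] < btc.G_in

    def test_btc_satisfies_both_defining_conditions(self, ml_soma):
        btc = bif.find_btc(ml_soma)
        cusp = bif.find_cusp(ml_soma)
        assert btc.v_sigma == pytest.approx(cusp.v_sigma, abs=1e-8)
        assert btc.G_in == pytest.approx(cusp.G_in, abs=1e-8)
        bt = bif.find_bt(ml_soma, btc.tau_delta)
        assert bt.G_in == pytest.approx(btc.G_in, abs=1e-4)


class TestHopf:
    def test_zero_tau_matches_point_model_jacobian(self, ml_soma):
        # at tau_delta = 0 the located Hopf must be a trace-zero point of the
        # 2x2 point-model Jacobian with det = omega^2
        pt = bif.find_hopf(ml_soma, 5.2, 0.0)
        system = ds_system(5.2, 0.0)
        J = system.jacobian(system.state_from_vsigma(pt.v_sigma), pt.I_ext)
        assert np.trace(J) == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(J) == pytest.approx(pt.aux["omega_H"] ** 2, rel=1e-6)

    def test_no_hopf_below_bt(self, ml_soma):
        with pytest.raises(ValueError, match="below the BT"):
            bif.find_hopf(ml_soma, 4.0, 10.0)

    def test_criticality_switches_across_btc(self, ml_soma):
        # the Hopf emerging from the BT point is subcritical below the BTC
        # time constant and supercritical above it
        btc = bif.find_btc(ml_soma)
        lo = bif.find_bt(ml_soma, btc.tau_delta - 2.0)
        hi = bif.find_bt(ml_soma, btc.tau_delta + 2.0)
        h_lo = bif.find_hopf(ml_soma, lo.G_in + 0.02, btc.tau_delta - 2.0,
                             criticality=True)
        h_hi = bif.find_hopf(ml_soma, hi.G_in + 0.02, btc.tau_delta + 2.0,
                             criticality=True)
        assert h_lo.aux["criticality"] == "subcritical"
        assert h_hi.aux["criticality"] == "supercritical"


def test_build_diagram_shapes(ml_soma):
    grid = np.linspace(3.0, 5.6, 8)
    diag = bif.build_diagram(ml_soma, [0.0, 10.0], grid)
    kinds = set(diag.points["kind"])
    assert {"SN_low", "SN_high", "cusp", "BT", "BTC"} <= kinds
    sn = diag.curve("SN_high")
    assert (np.diff(sn.sort_values("G_in")["I_ext"]) > 0).all()
    hopf0 = diag.points[(diag.points.kind == "Hopf") & (diag.points.tau_delta == 0.0)]
    assert len(hopf0) >= 2  # branch exists above G_BT(0) = 4.77 within the grid
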