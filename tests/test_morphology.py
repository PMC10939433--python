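"""SWC trees, the synthetic arbour generator, and the Rall reduction."""
import numpy as np
import pytest

from dendrosoma import morphology as morph

MEMB = dict(c_delta=1.0, g_delta=0.4, r_a=150.0)
GS = 2.0


class TestSWC:
    STICK = """# three-point stick
1 1 0 0 0 5 -1
2 3 50 0 0 1 1
3 3 100 0 0 1 2
"""

    def test_three_point_stick(self, tmp_path):
        p = tmp_path / "stick.swc"
        p.write_text(self.STICK)
        tree = morph.read_swc(p)
        assert tree.n_segments() == 2
        assert tree.root.type_code == 1
        assert {n.type_code for n in tree.nodes if n.parent != -1} == {3}

    def test_round_trip_identity(self, tmp_path):
        tree = morph.generate_arbor(seed=5, depth=3)
        p = tmp_path / "arbor.swc"
        morph.write_swc(tree, p)
        back = morph.read_swc(p)
        assert len(back.nodes) == len(tree.nodes)
        for a, b in zip(tree.nodes, back.nodes):
            assert (a.id, a.type_code, a.parent) == (b.id, b.type_code, b.parent)
            assert np.allclose([a.x, a.y, a.z, a.radius],
                               [b.x, b.y, b.z, b.radius], rtol=1e-5)

    def test_parse_error_reports_line(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 x 0 0 1 1\n")
        with pytest.raises(ValueError, match=":2:"):
            morph.read_swc(p)

    def test_orphan_node_rejected(self, tmp_path):
        p = tmp_path / "orphan.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 99\n")
        with pytest.raises(ValueError, match="parent"):
            morph.read_swc(p)


class TestGenerator:
    def test_depth_zero_single_cable(self):
        tree = morph.generate_arbor(seed=0, depth=0, n_stems=1)
        assert tree.n_segments() == 1

    def test_fixed_seed_is_deterministic(self):
        a = morph.generate_arbor(seed=11, depth=3, rall_exact=False)
        b = morph.generate_arbor(seed=11, depth=3, rall_exact=False)
        assert all((n.x, n.y, n.z, n.radius) == (m.x, m.y, m.z, m.radius)
                   for n, m in zip(a.nodes, b.nodes))
        c = morph.generate_arbor(seed=12, depth=3, rall_exact=False)
        assert any((n.x, n.y, n.z) != (m.x, m.y, m.z)
                   for n, m in zip(a.nodes, c.nodes))

    def test_diameters_follow_three_halves_rule(self):
        tree = morph.generate_arbor(seed=2, depth=3)
        for n in tree.nodes:
            kids = tree.children(n.id)
            if n.parent != -1 and kids:
                d32 = sum((2 * k.radius) ** 1.5 for k in kids)
                assert d32 == pytest.approx((2 * n.radius) ** 1.5, rel=1e-9)


class TestReduction:
    def test_unbranched_cable_reduces_to_itself(self):
        tree = morph.generate_arbor(seed=0, depth=0, n_stems=1,
                                    stem_diameter=1.4, segment_ell=0.5)
        eq = morph.reduce_to_cable(tree, **MEMB, G_sigma=GS)
        assert eq.d_eq == pytest.approx(1.4, rel=1e-9)
        n = [m for m in tree.nodes if m.parent != -1][0]
        assert eq.L == pytest.approx(tree.segment_length(n), rel=1e-9)
        assert eq.mismatch < 1e-9

    def test_rall_tree_dc_conductance_matches_cylinder(self):
        # compartmental DC solve of the full tree vs the equivalent cylinder
        tree = morph.generate_arbor(seed=7, depth=3, n_stems=2)
        eq = morph.reduce_to_cable(tree, **MEMB, G_sigma=GS)
        spec = eq.dendrite_spec(tau_delta=2.5)
        g_tree = morph.tree_input_conductance(tree, MEMB["g_delta"],
                                              MEMB["r_a"], GS)
        assert abs(g_tree - spec.G_in(GS)) / g_tree < 0.005

    def test_imperfect_tree_reports_mismatch(self):
        tree = morph.generate_arbor(seed=7, depth=3, rall_exact=False,
                                    diameter_jitter=0.4)
        eq = morph.reduce_to_cable(tree, **MEMB, G_sigma=GS)
        assert eq.mismatch > 1e-3

    def test_empty_tree_gives_degenerate_cable(self):
        soma_only = morph.ArborTree([morph.ArborNode(1, 1, 0, 0, 0, 5.0, -1)])
        eq = morph.reduce_to_cable(soma_only, **MEMB, G_sigma=GS)
        assert eq.rho == 0.0


class TestGrowStages:
    def test_stages_nested_and_monotone(self):
        tree = morph.generate_arbor(seed=4, depth=3, n_stems=2)
        stages = morph.grow_stages(tree, 5)
        assert stages[0].n_segments() == 0  # bare soma first
        assert stages[-1].n_segments() == tree.n_segments()  # full arbour last
        gins = [morph.tree_input_conductance(s, MEMB["g_delta"], MEMB["r_a"], GS)
                if s.n_segments() else GS for s in stages]
        assert np.all(np.diff(gins) > 0)
        sizes = [len(s.nodes) for s in stages]
        for a, b in zip(stages, stages[1:]):
            assert {n.id for n in a.nodes} <= {n.id for n in b.nodes}
        assert np.all(np.diff(sizes) > 0)
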