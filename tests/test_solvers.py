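"""Exact fixation solvers: closed forms, symmetries, limits."""

import numpy as np
import pytest

import tempofix as tf


class TestMoran:
    def test_closed_form(self):
        assert tf.moran_probability(2.0, 2) == pytest.approx(2.0 / 3.0)
        assert tf.moran_probability(1.0, 6) == pytest.approx(1.0 / 6.0)
        assert tf.moran_probability(1e9, 5) == pytest.approx(1.0, abs=1e-8)

    def test_guards(self):
        with pytest.raises(ValueError):
            tf.moran_probability(1.2, 1)
        with pytest.raises(ValueError):
            tf.moran_probability(-1.0, 4)


class TestStatic:
    @pytest.mark.parametrize("n", [3, 4, 6, 8])
    def test_complete_graph_equals_moran(self, n):
        res = tf.fixation_static(tf.build_transition_matrix(tf.make_complete(n), 1.3))
        assert res.rho == pytest.approx(tf.moran_probability(1.3, n), abs=1e-10)

    def test_two_node_graph(self):
        # hand enumeration: the two-state walk gives rho = r/(r+1) * weight
        # of winning both contested steps = Moran value 2/3 at r=2
        res = tf.fixation_static(tf.build_transition_matrix(tf.make_complete(2), 2.0))
        assert res.rho == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_neutral_drift(self, graphs4):
        for g in graphs4:
            res = tf.fixation_static(tf.build_transition_matrix(g, 1.0))
            assert res.rho == pytest.approx(0.25, abs=1e-12)

    def test_boundary_values_and_range(self):
        res = tf.fixation_static(tf.build_transition_matrix(tf.make_star(4), 1.4))
        assert res.x_star[0] == 0.0 and res.x_star[-1] == 1.0
        assert np.all(res.x_star >= 0) and np.all(res.x_star <= 1)

    def test_result_frame_has_summary_row(self):
        res = tf.fixation_static(tf.build_transition_matrix(tf.make_star(3), 1.2))
        df = res.to_frame()
        assert df.iloc[-1]["state"] == "rho"
        assert df.iloc[-1]["fixation_probability"] == res.rho


class TestSwitching:
    def test_isothermal_pair_equals_moran(self):
        g1, g2 = tf.make_cycle(6), tf.make_complete_bipartite(3, 3)
        for tau in (1, 3):
            rho = tf.fixation_switching(g1, g2, tau, 1.2).rho
            assert rho == pytest.approx(tf.moran_probability(1.2, 6), abs=1e-10)

    def test_neutral_drift(self, star_complete_4):
        g1, g2 = star_complete_4
        for tau in (1, 2, 5):
            assert tf.fixation_switching(g1, g2, tau, 1.0).rho == pytest.approx(
                0.25, abs=1e-12
            )

    def test_identical_snapshots_reduce_to_static(self):
        g = tf.make_star(4)
        static = tf.fixation_static(tf.build_transition_matrix(g, 1.3)).rho
        for tau in (1, 4):
            assert tf.fixation_switching(g, g, tau, 1.3).rho == pytest.approx(
                static, abs=1e-12
            )

    def test_order_dependence(self, star_complete_4):
        g1, g2 = star_complete_4
        a = tf.fixation_switching(g1, g2, 1, 1.2).rho
        b = tf.fixation_switching(g2, g1, 1, 1.2).rho
        assert abs(a - b) > 1e-6

    def test_large_tau_approaches_first_snapshot(self, star_complete_4):
        g1, g2 = star_complete_4
        rho_star = tf.fixation_static(tf.build_transition_matrix(g1, 1.2)).rho
        d_small = abs(tf.fixation_switching(g1, g2, 1, 1.2).rho - rho_star)
        d_large = abs(tf.fixation_switching(g1, g2, 200, 1.2).rho - rho_star)
        assert d_large < d_small

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            tf.fixation_switching(tf.make_star(3), tf.make_star(4), 1, 1.2)


class TestRandomInit:
    def test_tau1_is_average_of_both_orders(self, star_complete_4):
        g1, g2 = star_complete_4
        ri = tf.fixation_random_init(g1, g2, 1, 1.2).rho
        a = tf.fixation_switching(g1, g2, 1, 1.2).rho
        b = tf.fixation_switching(g2, g1, 1, 1.2).rho
        assert ri == pytest.approx((a + b) / 2, abs=1e-12)

    def test_neutral_drift(self, star_complete_4):
        g1, g2 = star_complete_4
        for tau in (1, 3):
            assert tf.fixation_random_init(g1, g2, tau, 1.0).rho == pytest.approx(
                0.25, abs=1e-12
            )

    def test_identical_snapshots_reduce_to_static(self):
        g = tf.make_cycle(4)
        static = tf.fixation_static(tf.build_transition_matrix(g, 1.4)).rho
        assert tf.fixation_random_init(g, g, 3, 1.4).rho == pytest.approx(
            static, abs=1e-12
        )


class TestStochasticSwitching:
    def test_p_one_equals_random_init_tau1(self, star_complete_4):
        g1, g2 = star_complete_4
        ri = tf.fixation_random_init(g1, g2, 1, 1.2).rho
        st = tf.fixation_stochastic_switching(g1, g2, 1.0, 1.2).rho
        assert st == pytest.approx(ri, abs=1e-12)

    def test_neutral_drift(self, star_complete_4):
        g1, g2 = star_complete_4
        for p in (0.3, 0.7, 1.0):
            assert tf.fixation_stochastic_switching(g1, g2, p, 1.0).rho == (
                pytest.approx(0.25, abs=1e-12)
            )

    def test_identical_snapshots_reduce_to_static(self):
        g = tf.make_star(4)
        static = tf.fixation_static(tf.build_transition_matrix(g, 1.2)).rho
        for process in ("flip", "redraw"):
            rho = tf.fixation_stochastic_switching(
                g, g, 0.4, 1.2, process=process
            ).rho
            assert rho == pytest.approx(static, abs=1e-12)

    def test_processes_coincide_at_half(self, star_complete_4):
        g1, g2 = star_complete_4
        a = tf.fixation_stochastic_switching(g1, g2, 0.5, 1.3, process="flip").rho
        b = tf.fixation_stochastic_switching(g1, g2, 0.5, 1.3, process="redraw").rho
        assert a == pytest.approx(b, abs=1e-12)

    def test_p_out_of_range(self, star_complete_4):
        g1, g2 = star_complete_4
        with pytest.raises(ValueError):
            tf.fixation_stochastic_switching(g1, g2, 0.0, 1.2)
        with pytest.raises(ValueError):
            tf.fixation_stochastic_switching(g1, g2, 1.5, 1.2)
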