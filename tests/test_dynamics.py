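"""Unit dynamics: rectified drive, Euler integration, nodes, network loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import golsa as G
from golsa.dynamics import Gate, Layer, LayerParams, Network, Projection


def _proj(W, source="src", target="tgt", **kw):
    return Projection(source=source, target=target, W=np.asarray(W, float), **kw)


class TestRectifiedDrive:
    @pytest.mark.parametrize(
        "rows, acts, expected_E, expected_I",
        [
            ([[[0.5, -0.2]]], {"src": [1.0, 1.0]}, [0.5], [0.2]),
            ([[[0.0, 0.0]]], {"src": [1.0, 1.0]}, [0.0], [0.0]),
        ],
    )
    def test_single_projection_rectification(self, rows, acts, expected_E, expected_I):
        E, I = G.rectified_drive([_proj(w) for w in rows], {k: np.array(v) for k, v in acts.items()})
        np.testing.assert_allclose(E, expected_E)
        np.testing.assert_allclose(I, expected_I)

    def test_summation_across_projections(self):
        projs = [
            _proj([[1.0, 0.0]], source="a"),
            _proj([[0.0, -1.0]], source="b"),
        ]
        acts = {"a": np.array([0.3, 0.4]), "b": np.array([0.3, 0.4])}
        E, I = G.rectified_drive(projs, acts)
        np.testing.assert_allclose(E, [0.3])
        np.testing.assert_allclose(I, [0.4])

    def test_shape_mismatch_is_configuration_error(self):
        with pytest.raises(G.ConfigurationError):
            G.rectified_drive([_proj([[1.0, 0.0]])], {"src": np.array([1.0, 1.0, 1.0])})

    def test_gated_projection_contributes_nothing(self):
        proj = _proj([[1.0, 1.0]], gate=Gate("osc", "gt", 0.0))
        E, I = G.rectified_drive([proj], {"src": np.ones(2)}, {"osc": -0.5})
        np.testing.assert_allclose(E, [0.0])
        np.testing.assert_allclose(I, [0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        W=st.lists(st.floats(-2, 2, allow_nan=False), min_size=4, max_size=4),
        a=st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=2),
    )
    def test_drive_components_nonnegative_and_consistent(self, W, a):
        """E and I are nonnegative and E - I equals the raw summed drive."""
        Wm = np.array(W).reshape(2, 2)
        av = np.array(a)
        E, I = G.rectified_drive([_proj(Wm)], {"src": av})
        assert np.all(E >= 0) and np.all(I >= 0)
        np.testing.assert_allclose(E - I, Wm @ av, atol=1e-12)


class TestStepLayer:
    def test_pure_decay(self):
        p = LayerParams(n_units=1, tau=1.0, lam=1.0, eps=0.0)
        a = G.step_layer(np.array([0.5]), np.zeros(1), np.zeros(1), p, dt=0.1)
        np.testing.assert_allclose(a, [0.45])

    def test_shunting_excitation_saturates_at_one(self):
        p = LayerParams(n_units=1, tau=1.0, lam=0.0, eps=0.0)
        a = np.array([1.0])
        for E in (0.5, 10.0, 100.0):
            out = G.step_layer(a, np.array([E]), np.zeros(1), p, dt=0.1)
            assert out[0] <= 1.0
            np.testing.assert_allclose(out, a)  # (1-a)E term vanishes at a=1

    def test_fixed_point_matches_closed_form(self):
        # constant E, I=0, linear inhibition: a* = E / (lam + E)
        p = LayerParams(n_units=1, tau=1.0, lam=1.0, eps=0.0)
        a = np.zeros(1)
        for _ in range(20000):
            a = G.step_layer(a, np.array([1.0]), np.zeros(1), p, dt=0.01)
        assert abs(a[0] - 0.5) < 1e-4

    def test_shunting_vs_linear_inhibition_at_low_activity(self):
        """Shunting inhibition loses force as activity approaches zero."""
        lin = LayerParams(n_units=1, tau=1.0, lam=0.0, eps=0.0, inhibition="linear")
        shn = LayerParams(n_units=1, tau=1.0, lam=0.0, eps=0.0, inhibition="shunting")
        a0 = np.array([0.1])
        I = np.array([1.0])
        a_lin = G.step_layer(a0, np.zeros(1), I, lin, dt=0.05)
        a_shn = G.step_layer(a0, np.zeros(1), I, shn, dt=0.05)
        assert a_lin[0] < a_shn[0] < a0[0]

    def test_nonfinite_drive_reports_layer_name(self):
        p = LayerParams(n_units=1)
        with pytest.raises(G.NumericalError, match="gradient"):
            G.step_layer(np.array([0.5]), np.array([np.inf]), np.zeros(1), p, dt=0.01, name="gradient")

    def test_boundedness_under_random_drive(self):
        """Activations stay in [0, 1] over 10^4 random-drive steps."""
        rng = np.random.default_rng(0)
        p = LayerParams(n_units=8, tau=0.2, lam=1.0, eps=0.05)
        a = rng.uniform(0, 1, 8)
        for _ in range(10_000):
            E = rng.uniform(0, 5, 8)
            I = rng.uniform(0, 5, 8)
            a = G.step_layer(a, E, I, p, dt=0.01, noise=rng.standard_normal(8))
            assert np.all(a >= 0.0) and np.all(a <= 1.0)

    def test_noise_increment_variance_scales_with_dt(self):
        """Per-step variance ratio between dt and dt/4 is ~4 (sqrt(dt) scaling)."""
        rng = np.random.default_rng(42)
        p = LayerParams(n_units=1, tau=1.0, lam=0.0, eps=0.1)
        n = 40_000

        def increments(dt):
            noise = rng.standard_normal(n)
            return np.array([
                G.step_layer(np.zeros(1), np.zeros(1), np.zeros(1), p, dt, np.array([z]))[0]
                for z in noise
            ])

        v1 = np.var(increments(0.01))
        v2 = np.var(increments(0.0025))
        assert 3.5 < v1 / v2 < 4.5


class TestNodes:
    def test_oscillator_zero_crossings_and_sign(self):
        osc = G.oscillator(period=2.0)
        assert G.update_node(osc, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert G.update_node(osc, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert G.update_node(osc, 0.5) == pytest.approx(1.0)
        assert G.update_node(osc, 1.5) == pytest.approx(-1.0)

    def test_state_change_pulse_window(self):
        node = G.state_change_inhibitor(pulse_duration=0.3, strength=5.0)
        G.update_node(node, 1.0, state_changed=True)
        assert G.update_node(node, 1.15) == 5.0      # inside window
        assert G.update_node(node, 1.6) == 0.0       # outside window

    def test_unknown_kind_rejected(self):
        bad = G.Node("x", "mystery")
        with pytest.raises(G.ConfigurationError):
            G.update_node(bad, 0.0)


class TestNetwork:
    def _single_layer_net(self, **params):
        net = Network(dt=0.01, seed=0)
        net.add_layer(Layer("only", LayerParams(n_units=2, **params), a=np.array([0.8, 0.3])))
        return net

    def test_isolated_layer_decays_monotonically(self):
        net = self._single_layer_net(lam=1.0, eps=0.0)
        prev = net.layers["only"].a.copy()
        for _ in range(600):
            net.step()
            cur = net.layers["only"].a
            assert np.all(cur <= prev + 1e-15)
            prev = cur.copy()
        assert np.all(prev < 1e-2)

    def test_closed_gate_blocks_drive(self):
        net = Network(dt=0.01)
        net.add_layer(Layer("src", LayerParams(n_units=1, lam=0.0), a=np.array([1.0])))
        net.add_layer(Layer("tgt", LayerParams(n_units=1, lam=0.0)))
        net.add_node(G.scalar_node("gate_node", value=-1.0))
        net.add_projection(
            Projection("src", "tgt", np.array([[2.0]]), gate=Gate("gate_node", "gt", 0.0))
        )
        net.run(100)
        assert net.layers["tgt"].a[0] == 0.0

    def test_winner_take_all_dynamics(self):
        """Mutual inhibition: the initially larger unit silences the other."""
        net = Network(dt=0.01)
        net.add_layer(
            Layer("wta", LayerParams(n_units=2, tau=0.5, lam=1.0), a=np.array([0.6, 0.4]))
        )
        net.add_projection(
            Projection("wta", "wta", np.array([[1.5, -2.0], [-2.0, 1.5]]))
        )
        net.run(3000)
        a = net.layers["wta"].a
        assert a[1] < 1e-3 < a[0]

    def test_synchronous_update_is_deterministic(self):
        def run():
            net = Network(dt=0.01, seed=123)
            net.add_layer(Layer("L", LayerParams(n_units=3, lam=0.5)))
            traj = []
            for i in range(100):
                net.step(external_E={"L": np.array([1.0, 0.5, 0.0])})
                traj.append(net.layers["L"].a.copy())
            return np.array(traj)

        np.testing.assert_array_equal(run(), run())

    def test_layer_inhibitor_node_suppresses_activity(self):
        net = Network(dt=0.01)
        layer = Layer("L", LayerParams(n_units=1, lam=0.0), a=np.array([0.9]))
        layer.inhibitors = [Gate("inh", "gt", 0.0)]
        net.add_layer(layer)
        net.add_node(G.scalar_node("inh", value=1.0))
        net.step()
        assert net.layers["L"].a[0] == 0.0
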