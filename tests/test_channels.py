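"""Channel kinetics: printed rate-law values, singularity handling, gate
updates and current densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import entsim
from entsim.channels import (
    ChannelModel,
    GateSpec,
    advance_gate,
    channel_current,
    gate_rates,
    gate_steady_state,
    gate_time_constant,
    load_channels,
    temperature_factor,
)
from entsim.errors import ConfigurationError, InputError, StateCorruptionError


def gate(channel_map, chan, name):
    return next(g for g in channel_map[chan].gates if g.name == name)


class TestRateLaws:
    def test_kdr_activation_midpoint(self, channel_map):
        # logistic midpoint: exponent argument vanishes at -25 mV
        m = gate(channel_map, "kdr", "m")
        minf, tau = gate_rates(m, -25.0)
        assert minf == pytest.approx(0.5, abs=1e-12)
        assert tau > 0

    def test_nav13_m1_alpha_removable_singularity(self, channel_map):
        # L'Hopital limit of 0.4(v+31)/(1-exp(-(v+31)/4.5)) at v = -31
        m1 = gate(channel_map, "nav1.3", "m1")
        alpha, _ = gate_rates(m1, -31.0)
        assert alpha == pytest.approx(1.8, rel=1e-9)

    def test_kv7_symmetry_at_half_activation(self, channel_map):
        # alpha and beta are mirror images around v_h, so m_inf = 1/2 there
        for gname in ("m1", "m2"):
            g = gate(channel_map, "kv7.2", gname)
            vh = g.params["alpha"]["vh"]
            alpha, beta = gate_rates(g, vh)
            assert alpha == pytest.approx(beta, rel=1e-12)
            assert gate_steady_state(g, vh) == pytest.approx(0.5, rel=1e-12)

    def test_inactivation_midpoints(self, channel_map):
        m2 = gate(channel_map, "nav1.3", "m2")
        assert gate_steady_state(m2, -50.0) == pytest.approx(0.5, abs=1e-12)
        ka2 = gate(channel_map, "ka", "m2")
        assert gate_steady_state(ka2, -80.0) == pytest.approx(0.5, abs=1e-12)

    def test_rates_finite_nonnegative_everywhere(self, channels, vgrid):
        for ch in channels:
            for g in ch.gates:
                minf = gate_steady_state(g, vgrid)
                tau = gate_time_constant(g, vgrid)
                assert np.all(np.isfinite(minf)) and np.all(np.isfinite(tau))
                assert np.all((minf >= 0) & (minf <= 1))
                assert np.all(tau > 0)

    def test_singularity_continuity(self, channels):
        # rate laws with removable 0/0 points are continuous to 1e-9 across
        # +/- 1e-6 mV of the singular voltage
        for ch in channels:
            for g in ch.gates:
                for comp in ("alpha", "beta"):
                    spec = g.params.get(comp)
                    if not spec or spec.get("form") != "linexp":
                        continue
                    vh = spec["vh"]
                    a, b = gate_rates(g, np.array([vh - 1e-6, vh, vh + 1e-6]))
                    for r in (a, b):
                        # second central difference removes the (genuine)
                        # linear slope; any jump at the singular point remains
                        assert abs(r[0] + r[2] - 2 * r[1]) < 1e-9

    def test_steady_states_monotone(self, channels, vgrid):
        # activation gates non-decreasing, inactivation gates non-increasing
        for ch in channels:
            for g in ch.gates:
                minf = gate_steady_state(g, vgrid)
                d = np.diff(minf)
                increasing = minf[-1] >= minf[0]
                if increasing:
                    assert np.all(d >= -1e-12), f"{ch.name}/{g.name}"
                else:
                    assert np.all(d <= 1e-12), f"{ch.name}/{g.name}"

    def test_unknown_gate_form_rejected(self):
        with pytest.raises(ConfigurationError):
            GateSpec("x", 1, "nonsense", {})
        with pytest.raises(ConfigurationError):
            GateSpec("x", 0, "inf_tau", {})

    def test_nonfinite_voltage_rejected(self, channel_map):
        m = gate(channel_map, "kdr", "m")
        with pytest.raises(InputError):
            gate_rates(m, np.nan)

    def test_temperature_scaling(self, channel_map):
        assert temperature_factor(24.0) == 1.0
        m1 = gate(channel_map, "nav1.3", "m1")
        a24, b24 = gate_rates(m1, -40.0, T=24.0)
        a34, b34 = gate_rates(m1, -40.0, T=34.0)
        assert a34 == pytest.approx(2 * a24) and b34 == pytest.approx(2 * b24)
        # NaV1.7 rates are temperature-independent
        n17 = gate(channel_map, "nav1.7", "m1")
        assert gate_rates(n17, -40.0, 24.0)[0] == gate_rates(n17, -40.0, 34.0)[0]


class TestAdvanceGate:
    def test_fixed_point(self, channel_map):
        g = gate(channel_map, "kdr", "m")
        minf = float(gate_steady_state(g, -40.0))
        assert advance_gate(minf, g, -40.0, 7.0) == pytest.approx(minf, rel=1e-12)

    def test_relaxation_limit(self, channel_map):
        g = gate(channel_map, "kdr", "m")
        out = advance_gate(0.0, g, -40.0, 1e6)
        assert out == pytest.approx(float(gate_steady_state(g, -40.0)), abs=1e-12)

    def test_semigroup_property(self, channel_map):
        # n steps of dt equal one step of n*dt at clamped voltage
        g = gate(channel_map, "kv7.2", "m1")
        m = 0.1
        for _ in range(40):
            m = advance_gate(m, g, -30.0, 0.5)
        once = advance_gate(0.1, g, -30.0, 20.0)
        assert m == pytest.approx(float(once), rel=1e-12)

    def test_invalid_inputs(self, channel_map):
        g = gate(channel_map, "kdr", "m")
        with pytest.raises(InputError):
            advance_gate(0.5, g, -40.0, 0.0)
        with pytest.raises(StateCorruptionError):
            advance_gate(1.5, g, -40.0, 0.1)

    def test_matches_reference_ode_solution(self, channel_map):
        # Kv7.2 fast gate clamped at -30 mV from state 0 over 50 ms: the
        # exact exponential update must agree with an adaptive stiff solver
        # of dm/dt = alpha(1-m) - beta*m to <= 1e-6
        from scipy.integrate import solve_ivp

        g = gate(channel_map, "kv7.2", "m1")
        alpha, beta = (float(x) for x in gate_rates(g, -30.0))
        sol = solve_ivp(
            lambda t, y: alpha * (1 - y) - beta * y, (0.0, 50.0), [0.0],
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        m = 0.0
        for _ in range(2000):
            m = advance_gate(m, g, -30.0, 0.025)
        assert abs(float(m) - sol.y[0, -1]) < 1e-6

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        state=st.floats(0.0, 1.0),
        v=st.floats(-120.0, 60.0),
        dt=st.floats(1e-3, 10.0),
    )
    def test_stays_in_unit_interval(self, channels, state, v, dt):
        for ch in channels:
            for g in ch.gates:
                out = advance_gate(state, g, v, dt)
                assert 0.0 <= float(out) <= 1.0


class TestChannelCurrent:
    def test_zero_at_reversal(self, channels):
        for ch in channels:
            gates = [gate_steady_state(g, -40.0) for g in ch.gates]
            assert channel_current(ch, gates, ch.e_rev) == pytest.approx(0.0)

    def test_zero_when_closed(self, channel_map):
        ch = channel_map["kdr"]
        assert channel_current(ch, [0.0], -20.0) == 0.0

    def test_kdr_density_arithmetic(self, channel_map):
        # gbar 0.01 S/cm^2, m = 0.5, 50 mV driving force -> 0.25 mA/cm^2
        ch = channel_map["kdr"]
        i = channel_current(ch, [0.5], -35.0)
        assert i == pytest.approx(0.01 * 0.5 * 50.0, rel=1e-12)

    def test_linear_in_gbar_and_sign_flip(self, channel_map):
        ch = channel_map["kdr"]
        doubled = ChannelModel("kdr2", 2 * ch.gbar, ch.e_rev, ch.gates)
        v = np.array([-90.0, -85.0, -80.0])
        i1 = channel_current(ch, [0.5], v)
        i2 = channel_current(doubled, [0.5], v)
        assert np.allclose(i2, 2 * i1)
        assert i1[0] < 0 and i1[1] == 0 and i1[2] > 0

    def test_gate_value_out_of_range(self, channel_map):
        with pytest.raises(StateCorruptionError):
            channel_current(channel_map["kdr"], [1.2], -40.0)


class TestConfig:
    def test_default_set(self, channels):
        assert [c.name for c in channels] == [
            "nav1.3", "nav1.7", "kdr", "ka", "kv7.2",
        ]
        table = {c.name: c.gbar for c in channels}
        assert table["nav1.3"] == 0.01
        assert table["kdr"] == 0.01
        assert table["ka"] == 0.0014
        assert {c.name: c.e_rev for c in channels}["kdr"] == -85.0

    def test_override_and_removal(self):
        chans = entsim.default_channels(kv7_2=None, kdr={"gbar": 0.02})
        names = {c.name: c for c in chans}
        assert "kv7.2" not in names
        assert names["kdr"].gbar == 0.02

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            load_channels(overrides={"nope": {"gbar": 1.0}})
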