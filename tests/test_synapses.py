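"""Biexponential synapses and the slow-EPSP second-messenger cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entsim.errors import ConfigurationError, InputError, StateCorruptionError
from entsim.synapses import (
    CASCADE_RATES,
    CascadeState,
    biexp_conductance,
    biexp_peak_factor,
    biexp_peak_time,
    cascade_fixed_point,
    cascade_step,
    fast_epsp,
    gabaa,
    gabac,
    slow_epsp,
    slow_epsp_current,
    synapse_current,
)


class TestBiexp:
    def test_peak_time_closed_forms(self):
        # t_p = tau1*tau2/(tau2-tau1) * ln(tau2/tau1)
        assert biexp_peak_time(1.0, 5.0) == pytest.approx(2.0118, abs=5e-5)
        assert biexp_peak_time(20.0, 50.0) == pytest.approx(30.543, abs=5e-4)
        # closed-form extremum: exp(-t_p/5) - exp(-t_p/1) at t_p = 1.25*ln 5
        assert biexp_peak_factor(1.0, 5.0) == pytest.approx(0.534992, abs=5e-6)

    def test_invalid_time_constants(self):
        with pytest.raises(ConfigurationError):
            biexp_peak_time(5.0, 5.0)
        with pytest.raises(ConfigurationError):
            gabaa(tau_rise=6.0)

    @pytest.mark.parametrize("factory", [fast_epsp, gabaa, gabac])
    def test_peak_normalisation(self, factory):
        # the maximum of the single-event conductance equals the weight
        syn = factory(weight=0.37)
        syn.event_times = [0.0]
        t = np.linspace(0.0, 12 * syn.tau_decay, 200001)
        g = biexp_conductance(syn, t)
        assert g.max() == pytest.approx(0.37, rel=1e-6)
        assert np.all(g >= 0)

    def test_causality(self):
        syn = fast_epsp(weight=1.0, delay=3.0)
        syn.event_times = [10.0]
        assert biexp_conductance(syn, 12.9) == 0.0
        assert biexp_conductance(syn, 13.5) > 0.0

    def test_superposition(self):
        both = gabac(weight=0.2)
        both.event_times = [5.0, 28.0]
        t = np.linspace(0.0, 300.0, 4001)
        total = biexp_conductance(both, t)
        parts = np.zeros_like(t)
        for te in both.event_times:
            single = gabac(weight=0.2)
            single.event_times = [te]
            parts += biexp_conductance(single, t)
        assert np.allclose(total, parts, rtol=1e-12, atol=1e-15)

    def test_synapse_current_examples(self):
        assert synapse_current(0.01, 0.0, 0.0) == 0.0  # fast EPSP at reversal
        assert synapse_current(0.02, -35.0, -35.0) == 0.0  # chloride reversal
        assert synapse_current(0.001, -55.0, 0.0) == pytest.approx(-0.055)
        with pytest.raises(StateCorruptionError):
            synapse_current(-1e-6, -55.0, 0.0)


class TestCascade:
    def test_resting_fixed_point(self):
        s = CascadeState()
        out = cascade_step(s, 0.0, 0.5)
        assert (out.D, out.C, out.P) == (0.0, 0.0, 1.0)

    def test_closed_form_fixed_points_under_unit_agonist(self):
        # D* = a1/b1, C* = a2 D*^2/b2, P* = b3/(a3 C* + b3)
        fp = cascade_fixed_point(1.0)
        assert fp.D == pytest.approx(0.53659, abs=1e-5)
        assert fp.C == pytest.approx(0.23460, abs=1e-5)
        assert fp.P == pytest.approx(0.69928, abs=1e-4)

    def test_long_integration_reaches_fixed_point(self):
        s = CascadeState()
        for _ in range(60000):  # 300 s at 5 ms steps
            s = cascade_step(s, 1.0, 0.005)
        fp = cascade_fixed_point(1.0)
        assert s.D == pytest.approx(fp.D, rel=1e-6)
        assert s.C == pytest.approx(fp.C, rel=1e-6)
        assert s.P == pytest.approx(fp.P, rel=1e-6)

    def test_matches_adaptive_reference_over_60s(self):
        # pulse of agonist, then recovery; compare against solve_ivp
        from scipy.integrate import solve_ivp

        r = CASCADE_RATES

        def pulse(t):
            return 2.0 if 1.0 <= t < 3.0 else 0.0

        def rhs(t, y):
            D, C, P = y
            return [
                r["alpha1"] * pulse(t) - r["beta1"] * D,
                r["alpha2"] * D**2 - r["beta2"] * C,
                -r["alpha3"] * C * P + r["beta3"] * (1 - P),
            ]

        ref = solve_ivp(rhs, (0, 60), [0, 0, 1], method="LSODA",
                        rtol=1e-10, atol=1e-12, max_step=0.5)
        s = CascadeState()
        dt = 0.001
        for i in range(60000):
            s = cascade_step(s, pulse(i * dt), dt)
        assert s.D == pytest.approx(ref.y[0, -1], rel=1e-5, abs=1e-12)
        assert s.C == pytest.approx(ref.y[1, -1], rel=1e-5, abs=1e-10)
        assert s.P == pytest.approx(ref.y[2, -1], rel=1e-5)

    def test_recovery_monotone_with_terminal_rate_beta3(self):
        s = CascadeState(D=0.0, C=0.0, P=0.4)
        dt, ps = 0.01, [0.4]
        for _ in range(3000):
            s = cascade_step(s, 0.0, dt)
            ps.append(s.P)
        ps = np.asarray(ps)
        assert np.all(np.diff(ps) >= 0)
        # terminal approach 1 - P ~ exp(-beta3 t)
        gap = 1.0 - ps
        rate = -np.log(gap[-1] / gap[-501]) / (500 * dt)
        assert rate == pytest.approx(CASCADE_RATES["beta3"], rel=1e-3)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.0, 50.0), st.floats(1e-4, 0.01)),
                    min_size=1, max_size=60))
    def test_positivity_under_random_pulse_trains(self, train):
        s = CascadeState()
        for I, dt in train:
            s = cascade_step(s, I, dt)
            assert s.D >= 0 and s.C >= 0 and 0.0 <= s.P <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            cascade_step(CascadeState(), 1.0, 0.0)
        with pytest.raises(InputError):
            cascade_step(CascadeState(), -1.0, 0.01)
        with pytest.raises(StateCorruptionError):
            CascadeState(D=-1.0)


class TestSlowEpsp:
    def test_current_at_reversal_and_when_closed(self):
        syn = slow_epsp()
        assert slow_epsp_current(syn, -85.0) == 0.0  # v = E_K, P = 1
        syn.cascade = CascadeState(P=0.0)
        assert slow_epsp_current(syn, 0.0) == 0.0  # fully phosphorylated

    def test_agonist_pulses_sum(self):
        syn = slow_epsp(weight=2.0)
        syn.event_times = [0.0, 20.0]
        assert syn.agonist(10.0) == 2.0
        assert syn.agonist(30.0) == 4.0  # overlapping 50 ms pulses
        assert syn.agonist(75.0) == 0.0

    def test_single_event_depolarization_outlasts_10s(self):
        # a single presynaptic spike produces a depolarization whose duration
        # at 10% of peak exceeds 10 s (slow EPSPs last 10 s to minutes)
        import entsim

        syn = slow_epsp(weight=86.0)
        syn.event_times = [300.0]
        n = entsim.build_neuron(synapses=[syn])
        r = entsim.integrate(n, 25000.0)
        v = r.v_soma
        depol = v - v[int(250 / r.dt)]
        peak = depol.max()
        assert peak > 1.0
        above = np.flatnonzero(depol >= 0.1 * peak)
        duration_ms = (above[-1] - above[0]) * r.dt
        assert duration_ms >= 10000.0
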