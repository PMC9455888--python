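import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from osnef.synapses import (DoubleExpState, FilterParams, SynapseSpec, SynapseState,
                            filter_spikes, impulse_response, nmda_block, peak_time,
                            step_synapse)

taus = st.floats(min_value=2e-4, max_value=0.3)


class TestFilterParams:
    @given(a=taus, b=taus)
    @settings(max_examples=30, deadline=None)
    def test_swap_normalization(self, a, b):
        f1, f2 = FilterParams(a, b), FilterParams(b, a)
        assert f1.tau_rise == f2.tau_rise and f1.tau_fall == f2.tau_fall
        assert f1.tau_rise <= f1.tau_fall

    @pytest.mark.parametrize("bad", [(0.0, 0.1), (-1e-3, 0.1), (np.inf, 0.1)])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            FilterParams(*bad)


class TestImpulseResponse:
    @given(a=taus, b=taus)
    @settings(max_examples=20, deadline=None)
    def test_unit_dc_gain(self, a, b):
        # total delivered charge per spike per unit weight is conserved
        f = FilterParams(a, b)
        # split at the fast time scale so quadrature resolves the sharp rise
        mid = 20 * f.tau_rise
        i1, _ = quad(lambda t: impulse_response(f, t), 0, mid, limit=200)
        i2, _ = quad(lambda t: impulse_response(f, t), mid, 30 * f.tau_fall, limit=200)
        assert abs(i1 + i2 - 1.0) < 1e-6

    def test_confluent_limit_is_alpha_synapse(self):
        tau = 5e-3
        f = FilterParams(tau, tau)
        t = np.linspace(0, 0.05, 200)
        assert np.allclose(impulse_response(f, t), t / tau**2 * np.exp(-t / tau))

    def test_peak_time_closed_form(self):
        f = FilterParams(1e-3, 100e-3)
        expected = np.log(0.1 / 1e-3) * 1e-3 * 0.1 / (0.1 - 1e-3)
        assert np.isclose(peak_time(f), expected)
        assert np.isclose(peak_time(f), 4.652e-3, atol=1e-5)
        # the analytic peak maximizes the sampled response
        t = np.linspace(0, 0.05, 5001)
        h = impulse_response(f, t)
        assert abs(t[np.argmax(h)] - peak_time(f)) < 2e-5

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            impulse_response(FilterParams(), -0.01)


class TestFilterSpikes:
    def test_empty_train_is_zero(self):
        out = filter_spikes([np.array([])], FilterParams(), 1e-3, 1.0)
        assert np.all(out == 0.0)

    def test_single_spike_reproduces_impulse_response(self):
        # the state-space recursion is impulse invariant: a spike at t=0 yields
        # exactly the continuous h sampled on the grid
        f = FilterParams(2e-3, 50e-3)
        dt = 1e-3
        out = filter_spikes([np.array([0.0])], f, dt, 1.0)[:, 0]
        t = np.arange(1000) * dt  # output sample k carries h(k dt)
        assert np.allclose(out, impulse_response(f, t), atol=1e-12)

    @pytest.mark.parametrize("confluent", [False, True])
    def test_recursion_equals_direct_convolution(self, confluent):
        f = FilterParams(5e-3, 5e-3) if confluent else FilterParams(1e-3, 100e-3)
        dt, dur = 1e-3, 2.0
        rng = np.random.default_rng(11)
        raster = (rng.random((2000, 3)) < 0.03).astype(float)
        out = filter_spikes(raster, f, dt, dur)
        h = impulse_response(f, np.arange(2000) * dt)
        for j in range(3):
            conv = np.convolve(raster[:, j], h)[:2000]
            assert np.max(np.abs(out[:, j] - conv)) <= 1e-6 * h.max()

    def test_regular_train_converges_to_rate(self):
        # 40 Hz regular spiking -> filtered trace ~40 Hz after 5 tau_fall
        f = FilterParams(1e-3, 100e-3)
        dt = 1e-3
        times = np.arange(0, 3.0, 1 / 40.0)
        out = filter_spikes([times], f, dt, 3.0)[:, 0]
        tail = out[int(5 * f.tau_fall / dt):]
        assert abs(tail.mean() - 40.0) / 40.0 < 0.05

    def test_spike_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            filter_spikes([np.array([5.0])], FilterParams(), 1e-3, 1.0)


class TestSynapseFamilies:
    def test_zero_input_decays_to_zero(self):
        spec = SynapseSpec(kind="current")
        state = SynapseState(spec, 2, 1e-3)
        state, j = step_synapse(spec, state, np.array([1.0, 0.0]))
        peak = j.copy()
        for _ in range(5000):
            state, j = step_synapse(spec, state, np.zeros(2))
        assert np.all(np.abs(j) < 1e-6 * max(peak.max(), 1.0))

    def test_gaba_on_depolarized_cell_hyperpolarizes(self):
        # conductance synapse with E_rev = -70 on a cell at -60: current < 0
        spec = SynapseSpec(kind="conductance", reversal_potential=-70.0)
        state = SynapseState(spec, 1, 1e-3)
        for _ in range(20):
            state, g = step_synapse(spec, state, np.array([1.0]))
        v = -60.0
        assert g[0] > 0
        assert g[0] * (spec.reversal_potential - v) < 0

    def test_current_kind_refuses_reversal(self):
        with pytest.raises(ValueError):
            SynapseSpec(kind="current", reversal_potential=0.0)

    def test_nmda_requires_voltage(self):
        spec = SynapseSpec(kind="nmda")
        state = SynapseState(spec, 1, 1e-3)
        with pytest.raises(ValueError):
            step_synapse(spec, state, np.array([1.0]))


class TestNmdaBlock:
    def test_small_at_hyperpolarized(self):
        assert nmda_block(-90.0) < 0.1

    def test_strictly_increasing_and_bounded(self):
        v = np.linspace(-120, 0, 200)
        b = nmda_block(v)
        assert np.all(np.diff(b) > 0)
        assert np.all((b > 0) & (b < 1))

    def test_scales_synaptic_conductance(self):
        spec = SynapseSpec(kind="nmda")
        s_lo = SynapseState(spec, 1, 1e-3)
        s_hi = SynapseState(spec, 1, 1e-3)
        for _ in range(10):
            _, g_lo = step_synapse(spec, s_lo, np.array([1.0]), post_voltage=-80.0)
            _, g_hi = step_synapse(spec, s_hi, np.array([1.0]), post_voltage=-20.0)
        assert g_hi[0] > g_lo[0] > 0


def test_double_exp_state_output_matches_step():
    f = FilterParams(1e-3, 30e-3)
    s = DoubleExpState(f, 1, 1e-3)
    y = s.step(np.array([1.0]))
    assert np.allclose(s.output, y)
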