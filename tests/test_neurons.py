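import numpy as np
import pytest
from scipy.optimize import fsolve

from osnef import neurons
from osnef.neurons import IZHIKEVICH_PRESETS, NeuronParams, create, lif_rate, spikes_to_table

POINT_KINDS = ["relu_spiking", "lif", "izhikevich", "wilson"]
ALL_KINDS = POINT_KINDS + ["pyramidal", "interneuron"]


def run_for(model, drive, duration, collect_raster=False):
    n_steps = int(round(duration / model.dt))
    counts = np.zeros(model.n)
    raster = np.zeros((n_steps, model.n)) if collect_raster else None
    for k in range(n_steps):
        s = model.step(drive)
        counts += s
        if collect_raster:
            raster[k] = s
    return (counts, raster) if collect_raster else counts


class TestLIF:
    def test_silent_at_rest_with_zero_drive(self):
        m = create("lif", 5)
        assert run_for(m, np.zeros(5), 1.0).sum() == 0

    def test_rate_matches_closed_form_within_2pct(self):
        # a(J) = 1 / (tau_ref + tau_rc ln(1 + 1/(J-1))), threshold 1
        m = create("lif", 12)
        J = np.linspace(1.05, 10.0, 12)
        T = 8.0
        counts = run_for(m, J, T)
        simulated = counts / T
        analytic = 1.0 / (0.002 + 0.02 * np.log1p(1.0 / (J - 1.0)))
        assert np.all(np.abs(simulated - analytic) / analytic < 0.02)

    def test_subthreshold_silent(self):
        m = create("lif", 3)
        assert run_for(m, np.full(3, 0.95), 2.0).sum() == 0

    def test_nonfinite_drive_rejected(self):
        m = create("lif", 2)
        with pytest.raises(ValueError, match="non-finite"):
            m.step(np.array([1.0, np.nan]))

    def test_dt_above_stability_bound_rejected(self):
        m = create("lif", 1)
        with pytest.raises(ValueError, match="stability bound"):
            m.step(np.ones(1), dt=1.0)


class TestSpikingReLU:
    def test_constant_20hz_one_second(self):
        m = create("relu_spiking", 1)
        count = run_for(m, np.array([20.0]), 1.0)
        assert abs(count[0] - 20) <= 1

    def test_zero_rate_never_spikes(self):
        m = create("relu_spiking", 1)
        assert run_for(m, np.array([0.0]), 2.0)[0] == 0
        assert run_for(m, np.array([-15.0]), 1.0)[0] == 0  # rectified

    @pytest.mark.parametrize("rate,T", [(7.3, 1.0), (33.9, 2.5), (1.1, 4.0)])
    def test_count_is_floor_or_ceil_of_integrated_rate(self, rate, T):
        m = create("relu_spiking", 1)
        count = run_for(m, np.array([rate]), T)[0]
        assert count in (np.floor(rate * T), np.ceil(rate * T))


class TestIzhikevich:
    def test_regular_spiking_adapts(self):
        # current step -> inter-spike intervals non-decreasing over first 5 spikes
        m = create("izhikevich", 1)
        _, raster = run_for(m, np.array([10.0]), 2.0, collect_raster=True)
        times = np.nonzero(raster[:, 0])[0] * m.dt
        assert times.size >= 5
        isis = np.diff(times[:6])
        assert np.all(np.diff(isis) >= -1e-9)

    def test_presets_selectable(self):
        m = create("izhikevich", 1, preset="fast_spiking")
        assert m.a == IZHIKEVICH_PRESETS["fast_spiking"]["a"]

    def test_silent_at_rest(self):
        m = create("izhikevich", 2)
        assert run_for(m, np.zeros(2), 1.0).sum() == 0


class TestWilson:
    def test_subthreshold_converges_to_ode_fixed_point(self):
        # equilibrium oracle: root-find the three coupled ODEs' right-hand sides
        m = create("wilson", 1)
        J = 0.1  # subthreshold

        def rhs(state):
            return m.rhs(*(np.array([v]) for v in state), J)

        eq = fsolve(lambda s: np.concatenate(rhs(s)), x0=[-0.75, 0.28, 0.0], full_output=False)
        run_for(m, np.array([J]), 1.5)
        assert abs(m.V[0] - eq[0]) < 0.01
        assert abs(m.R[0] - eq[1]) < 0.01
        assert abs(m.H[0] - eq[2]) < 0.02

    def test_silent_at_rest_fires_when_driven(self):
        m = create("wilson", 2)
        counts = run_for(m, np.array([0.0, 1.0]), 2.0)
        assert counts[0] == 0
        assert counts[1] > 20  # repetitive firing

    def test_dt_above_bound_rejected(self):
        m = create("wilson", 1)
        with pytest.raises(ValueError, match="stability bound"):
            m.step(np.zeros(1), dt=1e-3)


class TestCompartmental:
    def test_pyramidal_shape_constraints(self):
        m = create("pyramidal", 2)
        assert len(m.comp_names) == 4
        assert set(m.comp_names) == {"soma", "basal", "proximal", "distal"}
        assert len(m.gbar) == 6

    def test_rests_quietly_and_returns_to_rest(self):
        m = create("pyramidal", 1)
        count = run_for(m, None, 1.0)
        assert count.sum() == 0
        v_rest = m.voltage("soma")[0]
        assert -75 < v_rest < -60
        # drive it, then release: back near rest within 500 ms
        drive = {"proximal": [(np.array([15.0]), 0.0)]}
        for _ in range(int(0.5 / m.dt)):
            m.step(drive)
        for _ in range(int(0.5 / m.dt)):
            m.step()
        assert abs(m.voltage("soma")[0] - v_rest) < 6.0

    def test_fires_repetitively_with_steady_conductance_and_adapts(self):
        m = create("pyramidal", 1)
        drive = {"proximal": [(np.array([12.0]), 0.0)], "basal": [(np.array([12.0]), 0.0)]}
        c1 = run_for(m, drive, 1.0)
        c2 = run_for(m, drive, 1.0)
        assert c1[0] >= 10
        assert c2[0] <= c1[0]  # calcium-dependent adaptation
        assert np.all(m.V > -120) and np.all(m.V < 60)

    def test_interneuron_fast_spiking(self):
        m = create("interneuron", 1)
        assert run_for(m, None, 0.5).sum() == 0
        rate = run_for(m, {"soma": [(np.array([20.0]), 0.0)]}, 1.0)[0]
        assert rate > 100  # fast-spiking regime

    def test_negative_conductance_rejected(self):
        m = create("pyramidal", 1)
        with pytest.raises(ValueError):
            m.step({"basal": [(np.array([-1.0]), 0.0)]})


class TestContracts:
    @pytest.mark.parametrize("kind", POINT_KINDS)
    def test_no_spikes_under_zero_drive_and_finite_state(self, kind):
        m = create(kind, 3)
        assert run_for(m, np.zeros(3), 0.5).sum() == 0

    @pytest.mark.parametrize("kind", ["lif", "izhikevich"])
    def test_halving_dt_changes_count_by_at_most_one(self, kind):
        drive = np.array([1.5]) if kind == "lif" else np.array([10.0])
        m1 = create(kind, 1)
        c1 = run_for(m1, drive, 1.0)[0]
        m2 = create(kind, 1, dt=m1.dt / 2)
        c2 = run_for(m2, drive, 1.0)[0]
        assert abs(c1 - c2) <= 1

    def test_neuron_params_validation(self):
        with pytest.raises(ValueError):
            NeuronParams(model_kind="hodgkin", dt=1e-3)
        with pytest.raises(ValueError):
            NeuronParams(model_kind="lif", dt=-1.0)

    def test_uniform_step_function(self):
        m = create("lif", 2)
        out = neurons.step(m, np.array([0.0, 2.0]))
        assert out.shape == (2,)


def test_spike_table_format():
    raster = np.zeros((10, 2))
    raster[3, 1] = 1
    raster[7, 0] = 1
    df = spikes_to_table(raster, 1e-3)
    assert list(df.columns) == ["neuron_id", "spike_time_s"]
    assert df.iloc[0].tolist() == [0, 0.007]
    assert df.iloc[1].tolist() == [1, 0.003]
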