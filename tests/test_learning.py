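import dataclasses

import numpy as np
import pytest

from osnef.encoding import TuningDistribution, sample_tuning
from osnef.learning import (LearningConfig, OracleStream, SourceSpec, encoder_update,
                            pes_update, train_population)


class TestEncoderUpdate:
    def test_zero_at_activity_match(self):
        d = np.ones((5, 1))
        a_pre = np.full(5, 20.0)
        a = np.full(3, 15.0)
        delta = encoder_update(d, a_pre, a, a, alpha_e=1e-4)
        assert np.allclose(delta, 0.0)

    def test_worked_example_magnitude_and_direction(self):
        # sign(d)=+1, a_pre=20, a_pop=30, a_tar=40: |delta| = 1e-5*20*10 = 2e-3,
        # signed to increase the drive (pop underactive)
        delta = encoder_update(np.array([[1.0]]), np.array([20.0]), np.array([30.0]),
                               np.array([40.0]), alpha_e=1e-5)
        assert np.isclose(abs(delta[0, 0, 0]), 2e-3)
        assert delta[0, 0, 0] > 0

    def test_silent_presynaptic_neuron_frozen(self):
        delta = encoder_update(np.array([[1.0], [1.0]]), np.array([0.0, 10.0]),
                               np.array([5.0]), np.array([9.0]), alpha_e=1e-3)
        assert np.allclose(delta[0], 0.0)
        assert not np.allclose(delta[1], 0.0)

    def test_sign_of_zero_decoder_gates_update(self):
        delta = encoder_update(np.array([[0.0]]), np.array([10.0]), np.array([5.0]),
                               np.array([9.0]), alpha_e=1e-3)
        assert np.allclose(delta, 0.0)

    def test_printed_sign_flips_direction(self):
        args = (np.array([[1.0]]), np.array([20.0]), np.array([30.0]), np.array([40.0]), 1e-5)
        assert np.allclose(encoder_update(*args), -encoder_update(*args, printed_sign=True))

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            encoder_update(np.ones((1, 1)), np.array([-1.0]), np.array([0.0]),
                           np.array([0.0]), 1e-5)


class TestPesUpdate:
    def test_zero_at_decode_match(self):
        x = np.array([0.4, -0.2])
        delta = pes_update(np.full(10, 20.0), x, x, alpha_d=1e-3, n_pre=10)
        assert np.allclose(delta, 0.0)

    def test_worked_example(self):
        # N=1, a=10, x_hat=0.5, x=0.3: |delta| = 1e-3*10*0.2 = 2e-3, reducing the decode
        delta = pes_update(np.array([10.0]), np.array([0.5]), np.array([0.3]),
                           alpha_d=1e-3, n_pre=1)
        assert np.isclose(abs(delta[0, 0]), 2e-3)
        assert delta[0, 0] < 0  # decode too high -> decoder decreases

    def test_silent_neuron_unchanged(self):
        delta = pes_update(np.array([0.0, 10.0]), np.array([0.5]), np.array([0.0]),
                           alpha_d=1e-3, n_pre=2)
        assert np.allclose(delta[0], 0.0)


def _single_neuron_setup(pop_kind, seed=4):
    pre = sample_tuning(TuningDistribution(n=100, dims=1, seed=1))
    tar = sample_tuning(TuningDistribution(n=1, dims=1, seed=2))
    tar.encoders[:] = 1.0
    tar.x_intercepts[:] = -0.3
    tar.max_rates[:] = 35.0
    tar.gain = tar.max_rates / (1 - tar.x_intercepts)
    tar.bias = -tar.gain * tar.x_intercepts
    pop = dataclasses.replace(tar, kind=pop_kind)
    return pre, pop, tar


class TestTrainPopulation:
    def test_zero_rates_are_a_no_op(self):
        pre, pop, tar = _single_neuron_setup("lif")
        cfg = LearningConfig(alpha_e=0.0, alpha_d=0.0, duration=2.0)
        conn, log = train_population(pre, pop, OracleStream(tar=tar), cfg)
        # encoder tensor still at its (seeded) initialization; PES decoders at
        # their analytic initialization
        cfg2 = LearningConfig(alpha_e=0.0, alpha_d=0.0, duration=2.0)
        conn2, _ = train_population(pre, pop, OracleStream(tar=tar), cfg2)
        assert np.allclose(conn.encoder_tensor, conn2.encoder_tensor)
        assert np.allclose(conn.decoders.d, conn2.decoders.d)

    def test_training_reduces_activity_mismatch(self):
        pre, pop, tar = _single_neuron_setup("lif")
        cfg = LearningConfig(duration=30.0, signal_seed=3, seed=4)
        conn, log = train_population(pre, pop, OracleStream(tar=tar), cfg)
        early = log.activity_rmse.iloc[1:6].mean()
        late = log.activity_rmse.iloc[-5:].mean()
        assert late < early

    def test_self_target_control_reaches_spike_noise_floor(self):
        # a spiking-ReLU population trained toward its own tuning: the residual
        # mismatch is spike-discretization noise only (a few Hz)
        pre, pop, tar = _single_neuron_setup("relu_spiking")
        cfg = LearningConfig(duration=40.0, signal_seed=5, seed=6)
        conn, log = train_population(pre, pop, OracleStream(tar=tar), cfg)
        assert log.activity_rmse.iloc[-5:].mean() < 6.0

    def test_reproducible_under_fixed_seeds(self):
        pre, pop, tar = _single_neuron_setup("lif")
        cfg = LearningConfig(duration=5.0, signal_seed=7, seed=8)
        conn1, _ = train_population(pre, pop, OracleStream(tar=tar), cfg)
        conn2, _ = train_population(pre, pop, OracleStream(tar=tar), cfg)
        assert np.array_equal(conn1.weights, conn2.weights)

    def test_pes_descent_on_stationary_input(self):
        # start PES from deliberately halved decoders: the smoothed decode
        # error must descend toward the floor, not grow
        from osnef.encoding import Decoders, solve_decoders
        from osnef.learning import SourceSpec, train_connections
        from osnef.signals import bandlimited_noise

        pre, pop, tar = _single_neuron_setup("lif")
        grid = np.linspace(-1, 1, 201)[:, None]
        d0 = solve_decoders(pre.rates(grid), grid[:, 0])
        cfg = LearningConfig(alpha_e=0.0, alpha_d=1e-5, duration=25.0,
                             signal_seed=9, seed=10)
        sig = bandlimited_noise(1.0, cfg.duration, cfg.dt, seed=9)
        src = SourceSpec(pop=pre, signal=sig.values,
                         decoders=Decoders(d=0.5 * d0.d), name="pre")
        conns, log = train_connections([src], pop, OracleStream(tar=tar), cfg)
        smoothed = log.decode_rmse.rolling(5, min_periods=1).mean()
        assert smoothed.iloc[-1] < 0.6 * smoothed.iloc[2]
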