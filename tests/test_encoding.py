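import dataclasses

import numpy as np
import pytest

from osnef.encoding import (Decoders, TuningDistribution, compose_weights, decode_state,
                            empirical_tuning, encode_current, sample_tuning, solve_decoders)


def relu_population(n=100, dims=1, seed=0, **kw):
    return sample_tuning(TuningDistribution(n=n, dims=dims, seed=seed, **kw), "relu_spiking")


class TestSampleTuning:
    def test_relu_intercept_geometry(self):
        # x_int = -0.5, max_rate = 30 -> gain 20, bias 10; rate(1)=30, rate(-0.5)=0
        pop = relu_population(n=1, seed=3)
        pop.x_intercepts[:] = -0.5
        pop.max_rates[:] = 30.0
        pop.encoders[:] = 1.0
        pop.gain = pop.max_rates / (1 - pop.x_intercepts)
        pop.bias = -pop.gain * pop.x_intercepts
        assert np.isclose(pop.gain[0], 20.0) and np.isclose(pop.bias[0], 10.0)
        assert np.isclose(pop.rates(np.array([1.0]))[0], 30.0)
        assert np.isclose(pop.rates(np.array([-0.5]))[0], 0.0)

    def test_midpoint_rate(self):
        pop = relu_population(n=1)
        pop.x_intercepts[:] = 0.0
        pop.max_rates[:] = 40.0
        pop.encoders[:] = 1.0
        pop.gain = pop.max_rates / (1 - pop.x_intercepts)
        pop.bias = -pop.gain * pop.x_intercepts
        assert np.isclose(pop.rates(np.array([0.5]))[0], 20.0)

    def test_same_seed_identical(self):
        a, b = relu_population(seed=9), relu_population(seed=9)
        for attr in ("encoders", "gain", "bias", "x_intercepts", "max_rates"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))

    def test_sampled_intercepts_realized_exactly(self):
        pop = relu_population(n=200, seed=1)
        for i in range(0, 200, 17):
            x = pop.x_intercepts[i] * pop.encoders[i]
            assert abs(pop.rates(x)[i]) < 1e-9
            assert np.isclose(pop.rates(pop.encoders[i])[i], pop.max_rates[i])

    def test_distribution_matches_declared_uniform(self):
        # KS-style sanity at n = 1000
        from scipy.stats import kstest

        pop = relu_population(n=1000, seed=5)
        assert kstest(pop.x_intercepts, "uniform", args=(-1, 2)).pvalue > 0.01
        assert kstest(pop.max_rates, "uniform", args=(20, 20)).pvalue > 0.01
        assert np.allclose(np.abs(pop.encoders), 1.0)

    def test_encoders_unit_norm_2d(self):
        pop = relu_population(dims=2, seed=2)
        assert np.allclose(np.linalg.norm(pop.encoders, axis=1), 1.0)

    def test_degenerate_ranges_rejected(self):
        with pytest.raises(ValueError):
            TuningDistribution(n=10, x_intercept_range=(0.5, 0.5))

    def test_lif_tuning_realizes_intercept_and_max_rate(self):
        pop = sample_tuning(TuningDistribution(n=50, seed=4), "lif")
        # at the intercept the current equals threshold; at the edge, max rate
        for i in range(0, 50, 11):
            x = pop.x_intercepts[i] * pop.encoders[i]
            assert np.isclose(pop.current(x)[i], 1.0)
            assert np.isclose(pop.rates(pop.encoders[i])[i], pop.max_rates[i], rtol=1e-6)


class TestEncodeCurrent:
    def test_worked_example(self):
        pop = relu_population(n=1, dims=2)
        pop.encoders[:] = [0.6, 0.8]
        pop.gain[:] = 2.0
        pop.bias[:] = 1.0
        assert np.isclose(encode_current(np.array([1.0, 0.0]), pop)[0], 2.2)

    def test_zero_state_gives_bias(self):
        pop = relu_population(n=5, dims=2, seed=7)
        assert np.allclose(encode_current(np.zeros(2), pop), pop.bias)

    def test_orthogonal_state_gives_bias(self):
        pop = relu_population(n=1, dims=2)
        pop.encoders[:] = [1.0, 0.0]
        x = np.array([0.0, 0.73])
        assert np.allclose(encode_current(x, pop), pop.bias)

    def test_dimension_mismatch_rejected(self):
        pop = relu_population(dims=2)
        with pytest.raises(ValueError):
            encode_current(np.zeros(3), pop)


class TestDecodeState:
    def test_zero_activity_zero_estimate(self):
        d = Decoders(d=np.random.default_rng(0).normal(size=(10, 2)))
        assert np.allclose(decode_state(np.zeros(10), d), 0.0)

    def test_single_neuron(self):
        assert np.isclose(decode_state(np.array([10.0]), np.array([[0.05]]))[0], 0.5)

    def test_cancellation(self):
        d = np.array([[0.1], [-0.1]])
        assert np.isclose(decode_state(np.array([10.0, 10.0]), d)[0], 0.0)


class TestSolveDecoders:
    def test_identity_decode_rmse_under_002(self):
        # 100 ReLU tuning curves, f(x) = x: classic identity decode accuracy
        pop = relu_population(n=100, seed=12)
        grid = np.linspace(-1, 1, 201)[:, None]
        A = pop.rates(grid)
        d = solve_decoders(A, grid[:, 0])
        err = decode_state(A, d)[:, 0] - grid[:, 0]
        assert np.sqrt(np.mean(err**2)) < 0.02

    def test_zero_target_zero_decoders(self):
        pop = relu_population(n=30, seed=1)
        A = pop.rates(np.linspace(-1, 1, 50)[:, None])
        d = solve_decoders(A, np.zeros(50), ridge=0.1)
        assert np.allclose(d.d, 0.0)

    def test_duplicate_neurons_share_decoder_mass(self):
        # duplicated columns decode the same as one neuron with summed decoder
        pop = relu_population(n=20, seed=8)
        grid = np.linspace(-1, 1, 101)[:, None]
        A = pop.rates(grid)
        A_dup = np.hstack([A, A[:, :1]])
        d = solve_decoders(A, grid[:, 0], ridge=0.0)
        d_dup = solve_decoders(A_dup, grid[:, 0], ridge=0.0)
        est = decode_state(A, d)
        est_dup = decode_state(A_dup, d_dup)
        assert np.allclose(est, est_dup, atol=1e-8)
        # the duplicated column's decoder mass sums to the original's
        assert np.isclose(d_dup.d[0, 0] + d_dup.d[-1, 0], d.d[0, 0], atol=1e-8)

    def test_all_silent_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            solve_decoders(np.zeros((50, 10)), np.ones(50))

    def test_rmse_decreases_with_population_size(self):
        grid = np.linspace(-1, 1, 201)[:, None]
        errs = []
        for n in (10, 30, 100):
            trials = []
            for seed in range(5):
                pop = relu_population(n=n, seed=seed)
                A = pop.rates(grid)
                d = solve_decoders(A, grid[:, 0])
                e = decode_state(A, d)[:, 0] - grid[:, 0]
                trials.append(np.sqrt(np.mean(e**2)))
            errs.append(np.mean(trials))
        assert errs[0] > errs[1] > errs[2]


class TestComposeWeights:
    def test_scalar_example(self):
        w = compose_weights(np.array([[0.5]]), np.array([[2.0]]))
        assert np.isclose(w[0, 0], 1.0)

    def test_matrix_form_is_outer_product(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=(10, 2))
        e = rng.normal(size=(7, 2))
        assert np.allclose(compose_weights(d, e), d @ e.T)

    def test_tensor_form_matches_decode_then_encode(self):
        # w x-activity == encode(decode(activity)) when e_ij constant over i
        rng = np.random.default_rng(4)
        d = rng.normal(size=(10, 2))
        e_mat = rng.normal(size=(7, 2))
        e_tensor = np.broadcast_to(e_mat[None], (10, 7, 2)).copy()
        a = rng.random(10) * 30
        via_tensor = a @ compose_weights(d, e_tensor)
        via_chain = (a @ d) @ e_mat.T
        assert np.allclose(via_tensor, via_chain, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose_weights(np.ones((5, 2)), np.ones((4, 3)))


class TestEmpiricalTuning:
    def test_default_bin_count_is_21(self):
        import inspect

        from osnef.encoding import empirical_tuning as et

        assert inspect.signature(et).parameters["n_bins"].default == 21

    def test_constant_state_fills_one_bin(self):
        x = np.full(500, 0.33)
        a = np.full(500, 12.0)
        centers, mean, ci = empirical_tuning(x, a)
        filled = ~np.isnan(mean)
        assert filled.sum() == 1
        assert np.isclose(mean[filled][0], 12.0)

    def test_noiseless_relu_rates_recovered(self):
        pop = relu_population(n=1, seed=2)
        pop.encoders[:] = 1.0
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 5000)
        a = pop.rates(x[:, None])[:, 0]
        centers, mean, ci = empirical_tuning(x, a)
        expected = pop.rates(centers[:, None])[:, 0]
        bin_w = centers[1] - centers[0]
        assert np.all(np.abs(mean - expected) <= pop.gain[0] * bin_w)

    def test_misaligned_traces_rejected(self):
        with pytest.raises(ValueError):
            empirical_tuning(np.zeros(10), np.zeros(11))


def test_connection_factorization_consistency():
    rng = np.random.default_rng(5)
    pop_a = relu_population(n=6, seed=0)
    pop_b = relu_population(n=4, seed=1)
    from osnef.encoding import Connection
    from osnef.synapses import SynapseSpec

    d = Decoders(d=rng.normal(size=(6, 1)))
    e = rng.normal(size=(6, 4, 1))
    conn = Connection(pre=pop_a, post=pop_b, decoders=d, encoder_tensor=e,
                      synapse=SynapseSpec())
    assert np.allclose(conn.weights, np.einsum("id,ijd->ij", d.d, e))
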