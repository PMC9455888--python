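import numpy as np
import pytest

from osnef.drt import (DRTConfig, ForgettingFit, cleanup_wta, fit_forgetting,
                       unit_circle_cues)


class TestFitForgetting:
    def test_exact_recovery_of_generating_exponential(self):
        # y(t) = 0.9 exp(-t/5) on t in {0.5,...,10} -> B=0.9, tau=5, tau_half=5 ln 2
        t = np.array([0.5, 1, 2, 4, 6, 8, 10])
        y = 0.9 * np.exp(-t / 5.0)
        fit = fit_forgetting(t, y)
        assert np.isclose(fit.B, 0.9, atol=1e-6)
        assert np.isclose(fit.tau, 5.0, rtol=1e-4)
        assert np.isclose(fit.tau_half, 5.0 * np.log(2), rtol=1e-4)
        assert np.isclose(fit.tau_half, 3.466, atol=1e-3)

    def test_constant_accuracy_gives_infinite_tau(self):
        t = np.array([0.5, 1, 2, 4, 8])
        fit = fit_forgetting(t, np.ones_like(t))
        assert fit.B == 1.0
        assert np.isinf(fit.tau) and np.isinf(fit.tau_half)
        assert not fit.decaying

    def test_halved_accuracy_halves_B_keeps_tau(self):
        t = np.array([0.5, 1, 2, 4, 6, 8, 10])
        y = 0.8 * np.exp(-t / 3.0)
        f1 = fit_forgetting(t, y)
        f2 = fit_forgetting(t, y / 2)
        assert np.isclose(f2.B, f1.B / 2, rtol=1e-6)
        assert np.isclose(f2.tau, f1.tau, rtol=1e-6)

    def test_baseline_anchored_at_late_peak(self):
        # accuracy peaks at 2 s (slow attractor loading), then decays
        t = np.array([0.5, 1, 2, 4, 6, 8, 10])
        y = np.array([0.6, 0.8, 0.95, 0.7, 0.5, 0.35, 0.25])
        fit = fit_forgetting(t, y)
        assert fit.B <= 1.0
        assert fit.tau > 0 and fit.decaying
        # fitted curve passes through the anchor point (up to the B <= 1 cap)
        expected_B = min(1.0, 0.95 * np.exp(2.0 / fit.tau))
        assert np.isclose(fit.B, expected_B, rtol=1e-6)

    def test_b_capped_at_one(self):
        t = np.array([0.5, 1, 2, 4, 6])
        y = np.array([1.0, 1.0, 1.0, 0.5, 0.25])
        fit = fit_forgetting(t, y)
        assert fit.B <= 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_forgetting(np.array([1, 2]), np.array([1.0, 0.5]))


class TestCleanupWTA:
    def test_single_candidate_always_selected(self):
        assert cleanup_wta(np.array([0.1, -0.9]), np.array([[1.0, 0.0]])) == 0

    def test_exact_candidate_selected(self):
        cues = unit_circle_cues(8)
        assert cleanup_wta(cues[3], cues, mode="argmax") == 3
        assert cleanup_wta(cues[3], cues, mode="neural") == 3

    def test_tie_breaks_to_lowest_index(self):
        cands = np.array([[1.0, 0.0], [0.0, 1.0]])
        est = np.array([1.0, 1.0]) / np.sqrt(2)
        assert cleanup_wta(est, cands, mode="argmax") == 0

    def test_neural_agrees_with_argmax_oracle_under_margin(self):
        # >= 95% agreement on random estimates whose similarity margin > 0.1
        cues = unit_circle_cues(8)
        rng = np.random.default_rng(0)
        agree = total = 0
        while total < 60:
            est = rng.normal(scale=0.7, size=2)
            sims = np.sort(cues @ est)
            if sims[-1] - sims[-2] <= 0.1:
                continue
            total += 1
            if cleanup_wta(est, cues, mode="neural") == cleanup_wta(est, cues, mode="argmax"):
                agree += 1
        assert agree / total >= 0.95

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            cleanup_wta(np.array([1.0, 0.0]), np.zeros((0, 2)))


class TestDRTConfig:
    def test_cues_evenly_spaced_on_unit_circle(self):
        cfg = DRTConfig(n_cues=8)
        assert np.allclose(np.linalg.norm(cfg.cues, axis=1), 1.0)
        angles = np.arctan2(cfg.cues[:, 1], cfg.cues[:, 0])
        gaps = np.diff(np.unwrap(angles))
        assert np.allclose(gaps, 2 * np.pi / 8)

    def test_default_radius_is_half_neighbor_distance(self):
        cfg = DRTConfig(n_cues=8)
        d = np.linalg.norm(cfg.cues[0] - cfg.cues[1])
        assert np.isclose(cfg.correctness_radius, d / 2)
        # nearest-neighbor region: the true cue is inside, neighbors are not
        assert np.linalg.norm(cfg.cues[0] - cfg.cues[0]) <= cfg.correctness_radius
        assert np.linalg.norm(cfg.cues[1] - cfg.cues[0]) > cfg.correctness_radius

    def test_decreasing_delays_rejected(self):
        with pytest.raises(ValueError):
            DRTConfig(delays=(2.0, 1.0))

    def test_chance_is_one_over_candidates(self):
        assert DRTConfig(n_cues=8).chance == 0.125


class TestSummaryStatistics:
    def test_median_of_fits(self):
        fits = [ForgettingFit(B=b, tau=1.0, tau_half=np.log(2), residual=0.0)
                for b in (0.6, 0.9, 1.0)]
        assert np.median([f.B for f in fits]) == 0.9

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            ForgettingFit(B=1.4, tau=1.0, tau_half=0.7, residual=0.0)


class TestBiophysicalConstruction:
    def test_synapse_classes_and_trial_run_at_small_scale(self):
        """Biophysical wiring: feedforward AMPA, inhibitory GABA, trained
        recurrent/feedback NMDA onto pyramidal cells with an interneuron gate;
        a short trial runs without numeric failure."""
        from osnef.drt import DRTConfig, build_drt_network, run_trial

        cfg = DRTConfig(surrogate="biophysical", n_memory=8, n_interneuron=4,
                        train_duration=2.0, calibrate=False,
                        delays=(0.5, 1.0))
        net = build_drt_network(seed=5, cfg=cfg)
        by_pair = {(w.source, w.target): w for w in net.wires}
        assert by_pair[("pop", "pop")].synapse.kind == "nmda"
        assert by_pair[("pop", "diff")].synapse.kind == "nmda"
        assert by_pair[("pre", "diff")].synapse.kind == "conductance"
        assert by_pair[("pre", "diff")].synapse.reversal_potential == 0.0
        assert by_pair[("inh", "diff")].synapse.reversal_potential == -70.0
        assert net.populations["pop"].kind == "pyramidal"
        assert net.populations["inh"].kind == "interneuron"
        traj, selected, correct = run_trial(net, cfg.cues[0], delay=0.5, cfg=cfg)
        assert traj is not None and np.all(np.isfinite(traj))
        assert correct in (True, False)
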