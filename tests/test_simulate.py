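"""Generator invariants: determinism, perturbation chain, non-negativity, timelines."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from synvar import CohortConfig, make_ground_truth, synthesize_envelopes, synthesize_raw_trial
from synvar.simulate import (
    make_activation_profiles,
    pooled_activations,
    synthesize_velocity,
    task_directions,
)


def mean_matched_cos(A, B):
    S = A.T @ B
    ri, ci = linear_sum_assignment(-S)
    return float(np.mean(S[ri, ci]))


class TestGroundTruth:
    def test_zero_perturbation_collapses_chain(self):
        cfg = CohortConfig(n_subjects=2, n_repetitions=2, sigma_intra=0.0, sigma_inter=0.0, seed=3)
        truth = make_ground_truth(cfg)
        for s in range(2):
            np.testing.assert_allclose(truth.subject_W[s], truth.template_W, atol=1e-12)
            for r in range(2):
                np.testing.assert_allclose(truth.repetition_W[s, r], truth.template_W, atol=1e-12)

    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(n_subjects=2, n_repetitions=2, seed=11)
        a, b = make_ground_truth(cfg), make_ground_truth(cfg)
        assert np.array_equal(a.template_W, b.template_W)
        assert np.array_equal(a.repetition_W, b.repetition_W)

    def test_columns_unit_norm_nonneg(self):
        truth = make_ground_truth(CohortConfig(seed=5))
        assert np.all(truth.repetition_W >= 0)
        np.testing.assert_allclose(np.linalg.norm(truth.repetition_W, axis=-2), 1.0, atol=1e-12)

    def test_template_similarity_cap(self):
        cfg = CohortConfig(seed=9)
        W = make_ground_truth(cfg).template_W
        G = W.T @ W
        off = G[~np.eye(W.shape[1], dtype=bool)]
        assert np.max(off) < cfg.similarity_cap

    def test_unreachable_cap_raises(self):
        with pytest.raises(ValueError, match="0.01"):
            make_ground_truth(CohortConfig(similarity_cap=0.01, seed=1), max_redraws=5)

    def test_perturbation_ordering_monte_carlo(self):
        """Subject-level perturbation moves synergies further than repetition jitter."""
        inter_cos, intra_cos = [], []
        for seed in range(20):
            cfg = CohortConfig(n_subjects=4, n_repetitions=4, sigma_intra=0.05,
                               sigma_inter=0.3, seed=seed)
            t = make_ground_truth(cfg)
            for s in range(cfg.n_subjects):
                inter_cos.append(mean_matched_cos(t.template_W, t.subject_W[s]))
                for r in range(cfg.n_repetitions):
                    intra_cos.append(mean_matched_cos(t.subject_W[s], t.repetition_W[s, r]))
        assert np.mean(inter_cos) < np.mean(intra_cos)


class TestActivationProfiles:
    def test_preferred_direction_full_gain(self):
        cfg = CohortConfig(n_tasks=4, n_true_synergies=4, seed=2)
        truth = make_ground_truth(cfg)
        profiles = make_activation_profiles(truth, cfg)
        p = truth.activation_params
        dirs = task_directions(cfg)
        # tasks and synergies are both evenly spaced at 90 deg here: aligned pairs
        for d, k in [(0, 0), (1, 1), (2, 2), (3, 3)]:
            assert np.isclose(dirs[d], p.theta[k] % (2 * np.pi))
            # peak of the sampled burst reaches the gain (up to grid offset)
            assert profiles[d, k].max() == pytest.approx(p.gain[k], rel=0.01)

    def test_opposite_direction_silent(self):
        cfg = CohortConfig(n_tasks=4, n_true_synergies=4, seed=2)
        truth = make_ground_truth(cfg)
        profiles = make_activation_profiles(truth, cfg)
        # direction 2 is opposite synergy 0 (180 deg away)
        assert np.all(profiles[2, 0] == 0)

    def test_every_task_recruits_a_synergy(self, tiny_config):
        truth = make_ground_truth(tiny_config)
        profiles = make_activation_profiles(truth, tiny_config)
        assert np.all(profiles >= 0)
        assert np.all(profiles.sum(axis=(1, 2)) > 0)

    def test_bump_integral_matches_gaussian_closed_form(self):
        """Numeric quadrature of a burst vs gain * width * sqrt(2 pi), within 5%."""
        cfg = CohortConfig(samples_per_point=400, seed=2)
        truth = make_ground_truth(cfg)
        p = truth.activation_params
        profiles = make_activation_profiles(truth, cfg)
        d, k = 0, 0  # task 0 is synergy 0's preferred direction
        dt = 1.0 / cfg.samples_per_point
        integral = profiles[d, k].sum() * dt
        expected = p.gain[k] * p.width[k] * np.sqrt(2 * np.pi)
        assert integral == pytest.approx(expected, rel=0.05)


class TestEnvelopes:
    def test_noise_free_repetitions_identical(self):
        cfg = CohortConfig(n_subjects=2, n_repetitions=3, sigma_noise=0.0,
                           sigma_intra=0.0, seed=4)
        env = synthesize_envelopes(make_ground_truth(cfg), cfg)
        np.testing.assert_array_equal(env.envelopes[0, 0], env.envelopes[0, 1])
        np.testing.assert_array_equal(env.envelopes[0, 0], env.envelopes[0, 2])

    def test_nonnegative(self, tiny_cohort):
        assert np.all(tiny_cohort.envelopes >= 0)

    def test_noiseless_rank_equals_true_order(self):
        cfg = CohortConfig(n_subjects=1, n_repetitions=1, sigma_noise=0.0, seed=6)
        env = synthesize_envelopes(make_ground_truth(cfg), cfg)
        sv = np.linalg.svd(env.envelopes[0, 0], compute_uv=False)
        assert np.sum(sv > 1e-8 * sv[0]) == cfg.n_true_synergies

    def test_pooled_shape(self, tiny_cohort, tiny_config):
        c = tiny_config
        assert tiny_cohort.envelopes.shape == (
            c.n_subjects, c.n_repetitions, c.n_muscles, c.samples_per_point * c.n_tasks)

    def test_subject_max_normalization(self, tiny_matrices, tiny_config):
        for s in range(tiny_config.n_subjects):
            block = np.stack([tiny_matrices[(s, r)].values
                              for r in range(tiny_config.n_repetitions)])
            np.testing.assert_allclose(block.max(axis=(0, 2)), 1.0, atol=1e-12)


class TestVelocityAndRaw:
    def test_bell_count_and_peak_position(self):
        cfg = CohortConfig(seed=1)
        trace, windows = synthesize_velocity(cfg)
        assert len(windows) == cfg.n_tasks
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(trace.speed, height=0.5)
        assert len(peaks) == cfg.n_tasks
        for pk, w in zip(peaks, windows):
            mid = (w.onset + w.offset) / 2
            assert abs(pk / cfg.kin_rate - mid) < 2.0 / cfg.kin_rate

    def test_speed_zero_at_pause_centers(self):
        cfg = CohortConfig(seed=1)
        trace, windows = synthesize_velocity(cfg)
        peak = trace.speed.max()
        for w in windows:
            center = int((w.offset + cfg.pause_duration / 2) * cfg.kin_rate)
            assert trace.speed[center] < 0.01 * peak

    def test_raw_trial_deterministic(self):
        cfg = CohortConfig(n_subjects=1, n_repetitions=1, seed=8)
        truth = make_ground_truth(cfg)
        a = synthesize_raw_trial(truth, cfg, 0, 0)
        b = synthesize_raw_trial(truth, cfg, 0, 0)
        np.testing.assert_array_equal(a.emg, b.emg)

    def test_zero_tonic_silent_pauses(self):
        cfg = CohortConfig(n_subjects=1, n_repetitions=1, tonic_level=0.0,
                           sigma_noise=0.0, seed=8)
        truth = make_ground_truth(cfg)
        trial = synthesize_raw_trial(truth, cfg, 0, 0)
        t = np.arange(trial.emg.shape[1]) / cfg.emg_rate
        # center of the leading pause: no phasic, no tonic -> silence
        pause_mask = t < 0.4
        peak = np.abs(trial.emg).max()
        assert np.abs(trial.emg[:, pause_mask]).max() < 1e-3 * peak

    def test_rate_too_low_raises(self):
        cfg = CohortConfig(n_subjects=1, n_repetitions=1, emg_rate=500.0, seed=8)
        truth = make_ground_truth(cfg)
        with pytest.raises(ValueError, match="450"):
            synthesize_raw_trial(truth, cfg, 0, 0)

    def test_demodulated_raw_matches_planted_envelope(self):
        """Rectify + 10 Hz low-pass of the raw signal recovers the planted envelope."""
        from scipy import signal as sg
        cfg = CohortConfig(n_subjects=1, n_repetitions=1, sigma_noise=0.0, seed=1)
        truth = make_ground_truth(cfg)
        trial, env = synthesize_raw_trial(truth, cfg, 0, 0, return_envelope=True)
        sos = sg.butter(7, 10.0, btype="lowpass", fs=cfg.emg_rate, output="sos")
        demod = sg.sosfiltfilt(sos, np.abs(trial.emg), axis=-1)
        for ch in range(cfg.n_muscles):
            assert np.corrcoef(demod[ch], env[ch])[0, 1] >= 0.9
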