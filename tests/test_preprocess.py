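"""Signal-processing front end: smoothing, segmentation, filtering, tonic removal."""

import numpy as np
import pytest

from synvar import (
    CohortConfig,
    PhaseWindow,
    RawTrial,
    VelocityTrace,
    filter_envelope,
    make_ground_truth,
    normalize_and_pool,
    preprocess_cohort,
    preprocess_trial,
    remove_tonic,
    resample_phase,
    segment_phases,
    smooth_velocity,
    synthesize_raw_trial,
)
from synvar.simulate import synthesize_envelopes, synthesize_velocity


class TestSmoothVelocity:
    def test_constant_trace_unchanged(self):
        v = VelocityTrace(np.full(300, 2.5), kin_rate=100.0)
        out = smooth_velocity(v)
        np.testing.assert_allclose(out.speed, 2.5)

    def test_impulse_becomes_plateau(self):
        """A 0.2 s window at 100 Hz spans 21 samples: an impulse averages to 1/21."""
        speed = np.zeros(201)
        speed[100] = 1.0
        out = smooth_velocity(VelocityTrace(speed, kin_rate=100.0), window_s=0.2)
        plateau = out.speed[90:111]
        np.testing.assert_allclose(plateau, 1.0 / 21.0, atol=1e-12)
        assert out.speed[80] == 0.0

    def test_length_preserved_and_window_error(self):
        v = VelocityTrace(np.ones(50), kin_rate=100.0)
        assert smooth_velocity(v).speed.size == 50
        with pytest.raises(ValueError, match="longer than trace"):
            smooth_velocity(v, window_s=1.0)


class TestSegmentPhases:
    def test_recovers_generator_ground_truth(self):
        cfg = CohortConfig(seed=21)
        trace, true_windows = synthesize_velocity(cfg)
        windows = segment_phases(smooth_velocity(trace), cfg.n_tasks)
        assert len(windows) == cfg.n_tasks
        for w, t in zip(windows, true_windows):
            assert abs(w.onset - t.onset) <= 0.05
            assert abs(w.offset - t.offset) <= 0.05

    def test_single_bell(self):
        cfg = CohortConfig(n_tasks=1, seed=21)
        trace, _ = synthesize_velocity(cfg)
        (w,) = segment_phases(trace, 1)
        peak_t = np.argmax(trace.speed) / cfg.kin_rate
        assert w.onset < peak_t < w.offset

    def test_flat_trace_errors(self):
        with pytest.raises(ValueError, match="0 peaks"):
            segment_phases(VelocityTrace(np.zeros(500), kin_rate=100.0), 3)


class TestFilterEnvelope:
    def _trial(self, emg, rate=1000.0):
        n = emg.shape[1]
        v = VelocityTrace(np.zeros(int(n / rate * 100)), kin_rate=100.0)
        return RawTrial(emg=emg, channel_names=[f"M{i}" for i in range(emg.shape[0])],
                        emg_rate=rate, velocity=v)

    def test_dc_rejected(self):
        emg = np.full((2, 4000), 3.0)
        env = filter_envelope(self._trial(emg))
        assert np.abs(env).max() < 1e-6 * 3.0

    def test_low_frequency_tone_attenuated_40db(self):
        """A 5 Hz tone sits at 1/10 of the 50 Hz high-pass corner: > 40 dB down."""
        t = np.arange(8000) / 1000.0
        emg = np.sin(2 * np.pi * 5.0 * t)[None, :]
        from scipy import signal as sg
        sos = sg.butter(7, 50.0, btype="highpass", fs=1000.0, output="sos")
        hp = sg.sosfiltfilt(sos, emg, axis=-1)
        mid = slice(2000, 6000)  # avoid edges
        atten = np.sqrt(np.mean(hp[0, mid] ** 2)) / np.sqrt(np.mean(emg[0, mid] ** 2))
        assert atten < 10 ** (-40 / 20)

    def test_rate_too_low_raises(self):
        with pytest.raises(ValueError, match="high-pass"):
            filter_envelope(self._trial(np.zeros((1, 100)), rate=80.0))


class TestRemoveTonic:
    def test_constant_envelope_gives_zero_phasic(self):
        env = np.full((3, 2000), 0.7)
        w = PhaseWindow(onset=0.5, offset=1.5, task_index=0)
        phasic = remove_tonic(env, w, emg_rate=1000.0)
        np.testing.assert_allclose(phasic, 0.0, atol=1e-12)

    def test_ramp_endpoints_match_pad_means(self):
        rng = np.random.default_rng(0)
        env = rng.uniform(0.5, 1.5, (2, 2000))
        w = PhaseWindow(onset=0.5, offset=1.5, task_index=0)
        i0, on, off, i1 = 300, 500, 1500, 1700
        pre = env[:, i0:on].mean(axis=1)
        post = env[:, off:i1].mean(axis=1)
        seg = env[:, i0:i1]
        ramp = np.linspace(0, 1, seg.shape[1])
        tonic = pre[:, None] + (post - pre)[:, None] * ramp
        expected = np.clip(seg - tonic, 0, None)
        np.testing.assert_allclose(remove_tonic(env, w, 1000.0), expected, atol=1e-12)

    def test_bump_on_tonic_recovered(self):
        t = np.arange(3000) / 1000.0
        bump = np.exp(-((t - 1.0) ** 2) / (2 * 0.1 ** 2))
        env = (0.4 + bump)[None, :]
        w = PhaseWindow(onset=0.6, offset=1.4, task_index=0)
        phasic = remove_tonic(env, w, 1000.0)
        i0 = 400
        planted = bump[i0:1600]
        assert np.corrcoef(phasic[0], planted)[0, 1] >= 0.95

    def test_pad_outside_recording_raises(self):
        with pytest.raises(ValueError, match="padding"):
            remove_tonic(np.ones((1, 500)), PhaseWindow(0.1, 0.4, 0), 1000.0)


class TestResamplePhase:
    def test_linear_ramp_preserved(self):
        seg = np.linspace(0.0, 5.0, 37)[None, :]
        out = resample_phase(seg, 100)
        np.testing.assert_allclose(out[0], np.linspace(0.0, 5.0, 100), atol=1e-12)

    def test_identity_when_already_target_length(self):
        seg = np.random.default_rng(1).uniform(size=(2, 100))
        np.testing.assert_allclose(resample_phase(seg, 100), seg, atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            resample_phase(np.ones((1, 1)), 100)


class TestNormalizeAndPool:
    def _mats(self, rng, reps=3, tasks=4, m=5, p=20):
        return [[rng.uniform(0, 2, (m, p)) for _ in range(tasks)] for _ in range(reps)]

    def test_shape_and_unit_max(self, rng):
        mats = self._mats(rng)
        out = normalize_and_pool(mats, subject_id=0)
        assert len(out) == 3
        assert out[0].values.shape == (5, 80)
        stacked = np.stack([pm.values for pm in out])
        np.testing.assert_allclose(stacked.max(axis=(0, 2)), 1.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        mats = self._mats(rng)
        scaled = [[3.0 * m for m in rep] for rep in mats]
        a = normalize_and_pool(mats)
        b = normalize_and_pool(scaled)
        for x, y in zip(a, b):
            np.testing.assert_allclose(x.values, y.values, atol=1e-12)

    def test_zero_channel_left_at_zero(self, rng):
        mats = self._mats(rng)
        for rep in mats:
            for m in rep:
                m[2, :] = 0.0
        out = normalize_and_pool(mats)
        assert np.all(out[0].values[2] == 0)

    def test_inconsistent_channels_raise(self, rng):
        mats = [[rng.uniform(size=(5, 10))], [rng.uniform(size=(4, 10))]]
        with pytest.raises(ValueError, match="channel counts"):
            normalize_and_pool(mats)


class TestEndToEnd:
    def test_pipeline_shape_default_design(self):
        """One subject of the default design yields 16 x 900 named matrices."""
        cfg = CohortConfig(n_subjects=1, n_repetitions=2, seed=31)
        truth = make_ground_truth(cfg)
        trials = {(0, r): synthesize_raw_trial(truth, cfg, 0, r) for r in range(2)}
        mats = preprocess_cohort(trials, cfg.n_tasks)
        assert set(mats) == {(0, 0), (0, 1)}
        for pm in mats.values():
            assert pm.values.shape == (16, 900)
            assert pm.channel_names == cfg.channel_names
            assert np.all(pm.values >= 0)

    def test_envelope_recovery_noiseless(self):
        """Raw synthesis -> preprocessing recovers the planted phasic structure."""
        cfg = CohortConfig(n_subjects=1, n_repetitions=1, sigma_noise=0.0, seed=13)
        truth = make_ground_truth(cfg)
        trial = synthesize_raw_trial(truth, cfg, 0, 0)
        tasks = preprocess_trial(trial, cfg.n_tasks)
        planted = synthesize_envelopes(truth, cfg).clean[0, 0]
        P, pad, phase = cfg.samples_per_point, 0.2, cfg.phase_duration
        npad = int(round(P * pad / phase))
        cors = []
        for d, rec in enumerate(tasks):
            src = planted[:, d * P:(d + 1) * P]
            padded = np.concatenate(
                [np.zeros((16, npad)), src, np.zeros((16, npad))], axis=1)
            grid_src = np.linspace(0, 1, padded.shape[1])
            grid_dst = np.linspace(0, 1, P)
            exp = np.stack([np.interp(grid_dst, grid_src, padded[ch]) for ch in range(16)])
            for ch in range(16):
                if exp[ch].std() > 0 and rec[ch].std() > 0:
                    cors.append(np.corrcoef(rec[ch], exp[ch])[0, 1])
        assert np.mean(cors) >= 0.9
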