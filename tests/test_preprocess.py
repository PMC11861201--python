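"""Filtering, MVC normalization, downsampling, trimming and reordering."""

import numpy as np
import pytest

import myoface as mf
from myoface.core import EMGRecording, MUSCLES, NEUTRAL, PipelineError, Segment, TrialStructure
from myoface.preprocess import trim_transitions

FS = 1024.0


def _rec(x, stage="raw", fs=FS):
    return EMGRecording(np.tile(x, (7, 1)), fs=fs, stage=stage)


class TestBandpassRectify:
    def test_zero_in_zero_out(self):
        out = mf.bandpass_rectify(_rec(np.zeros(4096)))
        assert np.all(out.samples == 0)
        assert out.stage == "rectified"

    def test_output_nonnegative(self, rng):
        out = mf.bandpass_rectify(_rec(rng.standard_normal(4096)))
        assert out.samples.min() >= 0

    @pytest.mark.parametrize("freq, lo, hi", [(100.0, 0.95, 1.05), (5.0, 0.0, 0.2)])
    def test_passband_and_stopband(self, freq, lo, hi):
        t = np.arange(int(4 * FS)) / FS
        out = mf.bandpass_rectify(_rec(np.sin(2 * np.pi * freq * t)))
        mid = out.samples[0, 1024:-1024]
        assert lo <= mid.max() <= hi

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(PipelineError, match="corner"):
            mf.bandpass_rectify(_rec(np.zeros(1000), fs=800.0))

    def test_requires_raw_stage(self):
        with pytest.raises(PipelineError):
            mf.bandpass_rectify(_rec(np.ones(100), stage="rectified"))


class TestComputeMVC:
    def test_constant_signal_gives_constant_profile(self):
        prof = mf.compute_mvc(_rec(np.full(8192, 0.3), stage="rectified"))
        assert np.allclose(prof.values, 0.3, rtol=1e-6)

    def test_doubling_one_channel_scales_only_that_channel(self):
        x = np.tile(np.abs(np.sin(np.arange(8192) / 500)), (7, 1))
        rec = EMGRecording(x, fs=FS, stage="rectified")
        rec2 = EMGRecording(x * np.r_[2.0, np.ones(6)][:, None], fs=FS,
                            stage="rectified")
        p1 = mf.compute_mvc(rec).values
        p2 = mf.compute_mvc(rec2).values
        assert np.allclose(p2[0], 2 * p1[0])
        assert np.allclose(p2[1:], p1[1:])

    def test_dead_channel_rejected(self):
        x = np.ones((7, 4096))
        x[2] = 0.0
        with pytest.raises(ValueError, match="dead channel"):
            mf.compute_mvc(EMGRecording(x, fs=FS, stage="rectified"))

    def test_profile_tracks_programmed_maxima_at_zero_noise(self, zero_noise_task):
        # the AM Gaussian carrier makes the smoothed-rectified maximum sit a
        # reproducible ~10-15% above the programmed envelope peak; the bias is
        # common to both tasks and cancels under MVC normalization
        _, _, mvc = zero_noise_task
        prof = mf.compute_mvc(mf.bandpass_rectify(mvc.emg))
        ratio = prof.values / mvc.mvc_true
        assert np.all(ratio >= 1.0)
        assert np.all(ratio <= 1.3)
        assert ratio.std() < 0.05


class TestNormalizeAndEnvelope:
    def test_signal_at_mvc_level_normalizes_to_one(self):
        rec = _rec(np.full(int(10 * FS), 0.4), stage="rectified")
        prof = mf.MVCProfile(np.full(7, 0.4))
        env = mf.normalize_and_envelope(rec, prof)
        assert np.allclose(env.samples[:, 2048:-2048], 1.0, atol=1e-6)

    def test_zero_in_zero_out(self):
        env = mf.normalize_and_envelope(_rec(np.zeros(4096), stage="rectified"),
                                        mf.MVCProfile(np.ones(7)))
        assert np.all(env.samples == 0)

    def test_step_reaches_90_percent_within_half_second(self):
        x = np.zeros(int(15 * FS))
        x[int(5 * FS):] = 1.0
        env = mf.normalize_and_envelope(_rec(x, stage="rectified"),
                                        mf.MVCProfile(np.ones(7)))
        at = int((5 + 0.5) * FS)
        assert env.samples[0, at] >= 0.9

    def test_channel_mismatch_rejected(self):
        rec = EMGRecording(np.ones((7, 100)), fs=FS, stage="rectified")
        bad = mf.MVCProfile(np.ones(3), muscle_labels=("IF", "OF", "CS"))
        with pytest.raises(PipelineError):
            mf.normalize_and_envelope(rec, bad)


class TestDownsample:
    def test_one_second_gives_25_samples(self):
        env = _rec(np.ones(1024), stage="envelope")
        out = mf.downsample_to_video(env)
        assert out.n_samples == 25
        assert out.fs == 25

    def test_constant_preserved(self):
        out = mf.downsample_to_video(_rec(np.full(2048, 0.7), stage="envelope"))
        assert np.all(out.samples == 0.7)

    def test_upsampling_rejected(self):
        with pytest.raises(PipelineError):
            mf.downsample_to_video(_rec(np.ones(1024), stage="envelope"),
                                   fs_out=2000.0)

    def test_trimmed_reordered_trial_has_900_samples(self, participant_run):
        # 6 x (3 s neutral + 3 s expression) retained -> 36 s at 25 Hz
        assert participant_run.trials_25hz[0].shape == (7, 900)
        assert participant_run.trials[0].keypoints.n_samples == 900


def _toy_structure():
    segs = []
    t = 0.0
    for rep, label in enumerate(["anger", "fear"]):
        segs.append(Segment(0, rep, NEUTRAL, t, t + 5))
        segs.append(Segment(0, rep, label, t + 5, t + 10))
        t += 10
    return TrialStructure(segs)


class TestTrim:
    def test_five_second_segment_keeps_three(self):
        rec = _rec(np.ones(int(20 * FS)), stage="envelope")
        out, struct = trim_transitions(rec, _toy_structure(), margin=1.0)
        assert all(abs(s.duration_s - 3.0) < 1e-9 for s in struct)
        assert out.n_samples == int(12 * FS)

    def test_zero_margin_is_identity(self):
        rec = _rec(np.arange(int(20 * FS), dtype=float), stage="envelope")
        out, struct = trim_transitions(rec, _toy_structure(), margin=0.0)
        assert out is rec and struct is not None

    def test_retained_duration_bookkeeping(self):
        rec = _rec(np.ones(int(20 * FS)), stage="envelope")
        structure = _toy_structure()
        out, _ = trim_transitions(rec, structure, margin=0.5)
        removed = 2 * 0.5 * len(structure)
        assert abs(out.duration_s - (rec.duration_s - removed)) < 1e-9

    def test_short_segment_error_names_segment(self):
        segs = [Segment(0, 0, NEUTRAL, 0.0, 1.5), Segment(0, 0, "anger", 1.5, 6.5)]
        rec = _rec(np.ones(int(6.5 * FS)), stage="envelope")
        with pytest.raises(PipelineError, match="neutral"):
            trim_transitions(rec, TrialStructure(segs), margin=1.0)


@pytest.fixture(scope="module")
def reordered(small_cfg):
    expr = mf.generate_expression_task(small_cfg.generator, 0)
    env = EMGRecording(expr.truth.muscle_envelope, fs=1024.0, stage="envelope")
    return mf.reorder_trials(env, expr.structure, seed=13,
                             keypoints=expr.keypoints), small_cfg


class TestReorder:
    def test_each_expression_once_per_reordered_trial(self, reordered):
        trials, _ = reordered
        for t in trials:
            labels = [s.label for s in t.structure if s.label != NEUTRAL]
            assert sorted(labels) == sorted(mf.EXPRESSIONS)

    def test_union_covers_all_repetitions(self, reordered):
        trials, cfg = reordered
        seen = set()
        for t in trials:
            for s in t.structure:
                if s.label != NEUTRAL:
                    key = (s.trial, s.repetition)
                    assert key not in seen
                    seen.add(key)
        assert len(seen) == 6 * cfg.generator.n_repetitions

    def test_same_seed_same_ordering(self, small_cfg):
        expr = mf.generate_expression_task(small_cfg.generator, 0)
        env = EMGRecording(expr.truth.muscle_envelope, fs=1024.0, stage="envelope")
        a = mf.reorder_trials(env, expr.structure, seed=5)
        b = mf.reorder_trials(env, expr.structure, seed=5)
        assert all([s1 == s2 for t1, t2 in zip(a, b)
                    for s1, s2 in zip(t1.structure, t2.structure)])

    def test_unequal_repetitions_rejected(self):
        segs = [Segment(0, 0, NEUTRAL, 0, 5), Segment(0, 0, "anger", 5, 10),
                Segment(0, 1, NEUTRAL, 10, 15), Segment(0, 1, "anger", 15, 20),
                Segment(1, 0, NEUTRAL, 20, 25), Segment(1, 0, "fear", 25, 30)]
        rec = _rec(np.ones(int(30 * FS)), stage="envelope")
        with pytest.raises(PipelineError, match="repetition"):
            mf.reorder_trials(rec, TrialStructure(segs), seed=0)


@pytest.mark.parametrize("seed", [21, 22, 23])
def test_zero_noise_envelope_correlates_with_ground_truth(seed):
    gen = mf.GeneratorConfig(seed=seed, n_participants=1, n_repetitions=4,
                             noise=mf.NoiseConfig(0, 0, 0, 0))
    expr = mf.generate_expression_task(gen, 0)
    mvc = mf.generate_mvc_task(gen, 0)
    prof = mf.compute_mvc(mf.bandpass_rectify(mvc.emg))
    env = mf.normalize_and_envelope(mf.bandpass_rectify(expr.emg), prof)
    u_true = expr.truth.activation
    for c in range(7):
        r = np.corrcoef(env.samples[c], u_true[c])[0, 1]
        assert r > 0.99


def test_default_noise_envelope_still_tracks_ground_truth():
    gen = mf.GeneratorConfig(seed=21, n_participants=1, n_repetitions=4)
    expr = mf.generate_expression_task(gen, 0)
    mvc = mf.generate_mvc_task(gen, 0)
    prof = mf.compute_mvc(mf.bandpass_rectify(mvc.emg))
    env = mf.normalize_and_envelope(mf.bandpass_rectify(expr.emg), prof)
    u_true = expr.truth.activation
    for c in range(7):
        r = np.corrcoef(env.samples[c], u_true[c])[0, 1]
        assert r > 0.98


def test_io_roundtrip(tmp_path, rng):
    rec = EMGRecording(rng.random((7, 100)), fs=1024.0, stage="envelope")
    mf.core.write_emg_csv(tmp_path / "e.csv", rec)
    back = mf.core.read_emg_csv(tmp_path / "e.csv", stage="envelope")
    assert back.muscle_labels == MUSCLES
    assert np.allclose(back.samples, rec.samples)
    structure = _toy_structure()
    mf.core.write_structure_json(tmp_path / "s.json", structure)
    back_s = mf.core.read_structure_json(tmp_path / "s.json")
    assert back_s.segments == structure.segments
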