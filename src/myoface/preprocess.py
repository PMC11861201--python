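"""sEMG and keypoint preprocessing.

The raw 1024 Hz sEMG stream is band-pass filtered (20-450 Hz), full-wave
rectified, normalized per muscle by its maximum voluntary contraction (MVC)
value, and low-pass filtered at 2 Hz to obtain the activation envelope.
Both filters are zero-phase 4th-order Butterworth designs (applied forward
and backward with ``sosfiltfilt``), so the envelope stays aligned with the
25 Hz video-tracked keypoints.  The envelope is downsampled to the video
rate by selecting the sample nearest each 40 ms tick.

Around every transition between neutral and expression segments a 1 s
margin is discarded (electrode-friction artifacts and ramp transients),
and the single-expression trials are recombined into "reordered trials"
that each contain one repetition of all six expressions in random order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import (
    EMGRecording,
    KeypointTrajectories,
    MVCProfile,
    NEUTRAL,
    PipelineError,
    Segment,
    TrialStructure,
)

BANDPASS_HZ = (20.0, 450.0)
ENVELOPE_CUTOFF_HZ = 2.0
FILTER_ORDER = 4
TRIM_MARGIN_S = 1.0


def _bandpass_sos(fs: float):
    if fs <= 2 * BANDPASS_HZ[1]:
        raise PipelineError(
            f"sampling rate {fs} Hz too low for a {BANDPASS_HZ[1]} Hz corner")
    return signal.butter(FILTER_ORDER, BANDPASS_HZ, btype="bandpass",
                         fs=fs, output="sos")


def _lowpass_sos(fs: float, cutoff: float = ENVELOPE_CUTOFF_HZ):
    return signal.butter(FILTER_ORDER, cutoff, btype="lowpass", fs=fs, output="sos")


def bandpass_rectify(raw: EMGRecording) -> EMGRecording:
    """Zero-phase 20-450 Hz band-pass followed by full-wave rectification."""
    if raw.stage != "raw":
        raise PipelineError(f"expected raw recording, got stage {raw.stage!r}")
    sos = _bandpass_sos(raw.fs)
    filtered = signal.sosfiltfilt(sos, raw.samples, axis=1)
    return raw.with_samples(np.abs(filtered), stage="rectified")


def compute_mvc(mvc_rectified: EMGRecording) -> MVCProfile:
    """Per-muscle maximum of the 2 Hz-smoothed rectified MVC-task signal."""
    if mvc_rectified.stage != "rectified":
        raise PipelineError("compute_mvc expects a rectified recording")
    sos = _lowpass_sos(mvc_rectified.fs)
    smoothed = signal.sosfiltfilt(sos, mvc_rectified.samples, axis=1)
    return MVCProfile(smoothed.max(axis=1), mvc_rectified.muscle_labels)


def normalize_and_envelope(rectified: EMGRecording, mvc: MVCProfile) -> EMGRecording:
    """Divide each muscle by its MVC value, then 2 Hz zero-phase low-pass.

    Zero-phase filtering can undershoot below zero; the envelope is clipped
    at 0 to preserve the non-negativity NMF requires.
    """
    if rectified.stage != "rectified":
        raise PipelineError("normalize_and_envelope expects a rectified recording")
    if rectified.muscle_labels != mvc.muscle_labels:
        raise PipelineError("channel labels of recording and MVC profile differ")
    normalized = rectified.samples / mvc.values[:, None]
    sos = _lowpass_sos(rectified.fs)
    env = signal.sosfiltfilt(sos, normalized, axis=1)
    return rectified.with_samples(np.clip(env, 0.0, None), stage="envelope")


def video_tick_indices(fs_in: float, n_samples: int, fs_out: float) -> np.ndarray:
    """Indices of the samples nearest each 1/fs_out tick, starting at t = 0."""
    n_ticks = int(np.ceil(n_samples / fs_in * fs_out - 1e-9))
    idx = np.round(np.arange(n_ticks) / fs_out * fs_in).astype(int)
    return idx[idx < n_samples]


def downsample_to_video(envelope: EMGRecording, fs_out: float = 25.0) -> EMGRecording:
    """Pick the envelope sample nearest each 40 ms tick (no decimation filter).

    The 2 Hz envelope is band-limited far below the output Nyquist rate, so
    nearest-tick selection introduces no aliasing.
    """
    if envelope.stage != "envelope":
        raise PipelineError("downsample_to_video expects an envelope recording")
    if fs_out > envelope.fs:
        raise PipelineError("cannot downsample to a higher rate")
    idx = video_tick_indices(envelope.fs, envelope.n_samples, fs_out)
    return envelope.with_samples(envelope.samples[:, idx], stage="downsampled",
                                 fs=fs_out)


# ---------------------------------------------------------------------------
# transition trimming
# ---------------------------------------------------------------------------

def _slice_by_time(data, fs: float, start_s: float, end_s: float) -> np.ndarray:
    i0 = int(round(start_s * fs))
    i1 = int(round(end_s * fs))
    return data[:, i0:i1]


def trim_transitions(x, structure: TrialStructure, margin: float = TRIM_MARGIN_S):
    """Drop ``margin`` seconds adjacent to every label transition.

    ``x`` may be an :class:`EMGRecording` or :class:`KeypointTrajectories`;
    the same rule applies to both streams.  Returns the trimmed data and an
    updated structure whose segment times index into the trimmed stream.
    Recording edges are treated as transitions as well.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin == 0:
        return x, structure
    for seg in structure:
        if seg.duration_s < 2 * margin:
            raise PipelineError(
                f"segment {seg.label!r} (trial {seg.trial}, rep {seg.repetition}) "
                f"of {seg.duration_s:.3g} s is shorter than 2 x {margin} s margin")
    if isinstance(x, EMGRecording):
        data, fs = x.samples, x.fs
    else:
        data, fs = x.displacements, x.fs
    pieces = []
    new_segments = []
    t_cursor = 0.0
    for seg in structure:
        keep = (seg.start_s + margin, seg.end_s - margin)
        pieces.append(_slice_by_time(data, fs, *keep))
        dur = keep[1] - keep[0]
        new_segments.append(Segment(seg.trial, seg.repetition, seg.label,
                                    t_cursor, t_cursor + dur))
        t_cursor += dur
    trimmed = np.concatenate(pieces, axis=1)
    new_structure = TrialStructure(new_segments)
    if isinstance(x, EMGRecording):
        return x.with_samples(trimmed), new_structure
    return KeypointTrajectories(trimmed, fs=x.fs, point_labels=x.point_labels), new_structure


# ---------------------------------------------------------------------------
# trial reordering
# ---------------------------------------------------------------------------

@dataclass
class ReorderedTrial:
    """One repetition of each expression, spliced from the six source trials."""

    index: int
    emg: EMGRecording
    keypoints: KeypointTrajectories | None
    structure: TrialStructure


def _neutral_before(structure: TrialStructure, expr_seg: Segment) -> Segment:
    """The neutral segment immediately preceding an expression segment."""
    best = None
    for seg in structure:
        if seg.label == NEUTRAL and seg.trial == expr_seg.trial \
                and seg.end_s <= expr_seg.start_s + 1e-9:
            if best is None or seg.end_s > best.end_s:
                best = seg
    if best is None:
        raise PipelineError(f"no neutral context before segment {expr_seg}")
    return best


def reorder_trials(emg: EMGRecording, structure: TrialStructure, seed: int,
                   keypoints: KeypointTrajectories | None = None,
                   ) -> list[ReorderedTrial]:
    """Build reordered trials, one expression repetition per source trial.

    For repetition slot ``r``, one expression segment (with its flanking
    neutral context) is drawn without replacement from each of the six
    single-expression trials; the six draws are shuffled and concatenated.
    Every reordered trial therefore contains all six expressions exactly
    once, and the union over all slots is a partition of all repetitions.
    """
    rng = np.random.default_rng(seed)
    expr_segs = structure.expression_segments()
    by_trial: dict[int, dict[int, Segment]] = {}
    for seg in expr_segs:
        by_trial.setdefault(seg.trial, {})[seg.repetition] = seg
    trials = sorted(by_trial)
    if not trials:
        raise PipelineError("no expression segments in structure")
    n_rep = {t: len(by_trial[t]) for t in trials}
    n_slots = min(n_rep.values())
    if len(set(n_rep.values())) != 1:
        raise PipelineError(f"unequal repetition counts per trial: {n_rep}")

    # deal each trial's repetitions across slots, without replacement
    deal = {t: rng.permutation(sorted(by_trial[t])) for t in trials}

    out = []
    for slot in range(n_slots):
        order = rng.permutation(len(trials))
        pieces_emg, pieces_kp, segs = [], [], []
        t_cursor = 0.0
        for k in order:
            trial = trials[int(k)]
            expr_seg = by_trial[trial][int(deal[trial][slot])]
            neutral_seg = _neutral_before(structure, expr_seg)
            for seg in (neutral_seg, expr_seg):
                pieces_emg.append(_slice_by_time(emg.samples, emg.fs,
                                                 seg.start_s, seg.end_s))
                if keypoints is not None:
                    i0 = int(np.ceil(seg.start_s * keypoints.fs - 1e-9))
                    i1 = int(np.ceil(seg.end_s * keypoints.fs - 1e-9))
                    pieces_kp.append(keypoints.displacements[:, i0:i1])
                dur = seg.duration_s
                segs.append(Segment(seg.trial, seg.repetition, seg.label,
                                    t_cursor, t_cursor + dur))
                t_cursor += dur
        new_emg = emg.with_samples(np.concatenate(pieces_emg, axis=1))
        new_kp = None
        if keypoints is not None:
            new_kp = KeypointTrajectories(np.concatenate(pieces_kp, axis=1),
                                          fs=keypoints.fs,
                                          point_labels=keypoints.point_labels)
        out.append(ReorderedTrial(slot, new_emg, new_kp, TrialStructure(segs)))
    return out


def trim_reordered(trial: ReorderedTrial, margin: float = TRIM_MARGIN_S) -> ReorderedTrial:
    """Apply transition trimming to both streams of a reordered trial."""
    emg, struct = trim_transitions(trial.emg, trial.structure, margin)
    kp = None
    if trial.keypoints is not None:
        kp, _ = trim_transitions(trial.keypoints, trial.structure, margin)
    return ReorderedTrial(trial.index, emg, kp, struct)
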