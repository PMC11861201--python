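"""Shared containers and file schemas for facial sEMG analysis.

Canonical channel orders
------------------------
Seven facial muscle regions are recorded (1024 Hz surface EMG) and five
facial keypoints are tracked (25 Hz video):

* muscles:  IF, OF, CS, LLSAN, ZM, DAO, Me
  (inner/outer frontalis, corrugator supercilii, levator labii superioris
  alaeque nasi, zygomaticus major, depressor anguli oris, mentalis)
* keypoints: inner_eyebrow, outer_eyebrow, nose, mouth_corner, chin

All containers hold channels-by-time arrays in these fixed orders.
Segment times are half-open intervals [start_s, end_s) in seconds from the
start of the recording they index into.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MUSCLES = ("IF", "OF", "CS", "LLSAN", "ZM", "DAO", "Me")
KEYPOINTS = ("inner_eyebrow", "outer_eyebrow", "nose", "mouth_corner", "chin")
EXPRESSIONS = ("anger", "disgust", "fear", "happiness", "sadness", "surprise")
NEUTRAL = "neutral"
LABELS = (NEUTRAL,) + EXPRESSIONS

FS_EMG = 1024.0
FS_VIDEO = 25.0

#: processing stages of an EMG recording, in pipeline order
STAGES = ("raw", "bandpassed", "rectified", "normalized", "envelope", "downsampled")
_NONNEG_STAGES = frozenset({"rectified", "normalized", "envelope", "downsampled"})


class PipelineError(ValueError):
    """Raised when an operation is applied to data in the wrong state."""


@dataclass
class EMGRecording:
    """Multichannel sEMG, ``samples`` of shape (n_channels, n_samples).

    Raw units are mV; after MVC normalization the signal is a dimensionless
    fraction of maximum voluntary contraction.
    """

    samples: np.ndarray
    fs: float
    muscle_labels: tuple[str, ...] = MUSCLES
    stage: str = "raw"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.muscle_labels) != self.samples.shape[0]:
            raise ValueError("muscle_labels length must match channel count")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage in _NONNEG_STAGES and self.samples.size and self.samples.min() < 0:
            raise ValueError(f"stage {self.stage!r} requires non-negative samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray, *, stage: str | None = None,
                     fs: float | None = None) -> "EMGRecording":
        return replace(self, samples=samples,
                       stage=self.stage if stage is None else stage,
                       fs=self.fs if fs is None else fs)


@dataclass
class KeypointTrajectories:
    """Signed 1-D displacements of the five facial keypoints (5 x time).

    Each keypoint's displacement is the scalar projection of its motion onto
    its dominant axis (elevation-positive for eyebrows/nose/chin, zygomaticus
    pull-positive for the mouth corner).
    """

    displacements: np.ndarray
    fs: float = FS_VIDEO
    point_labels: tuple[str, ...] = KEYPOINTS

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 2 or self.displacements.shape[0] != len(self.point_labels):
            raise ValueError("displacements must be (n_points x time)")

    @property
    def n_samples(self) -> int:
        return self.displacements.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class Segment:
    trial: int
    repetition: int
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TrialStructure:
    """Ordered, non-overlapping labelled segments of a recording."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self):
        prev_end = -np.inf
        for seg in self.segments:
            if seg.label not in LABELS:
                raise ValueError(f"unknown label {seg.label!r}")
            if seg.end_s <= seg.start_s:
                raise ValueError(f"empty segment {seg}")
            if seg.start_s < prev_end - 1e-9:
                raise ValueError(f"overlapping segment {seg}")
            prev_end = seg.end_s

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s if self.segments else 0.0

    def expression_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.label != NEUTRAL]

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.segments:
            counts[s.label] = counts.get(s.label, 0) + 1
        return counts


@dataclass
class MVCProfile:
    """Per-muscle maximum of the smoothed rectified MVC-task signal (mV)."""

    values: np.ndarray
    muscle_labels: tuple[str, ...] = MUSCLES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.muscle_labels),):
            raise ValueError("one MVC value per muscle required")
        if np.any(self.values <= 0):
            dead = [m for m, v in zip(self.muscle_labels, self.values) if v <= 0]
            raise ValueError(f"dead channel(s) with non-positive MVC: {dead}")


# ---------------------------------------------------------------------------
# columnar file schemas
# ---------------------------------------------------------------------------

def write_emg_csv(path: str | Path, rec: EMGRecording) -> None:
    df = pd.DataFrame(rec.samples.T, columns=list(rec.muscle_labels))
    df.insert(0, "time_s", rec.times())
    df.to_csv(path, index=False)


def read_emg_csv(path: str | Path, stage: str = "raw") -> EMGRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else FS_EMG
    labels = tuple(c for c in df.columns if c != "time_s")
    return EMGRecording(df[list(labels)].to_numpy().T, fs=float(round(fs, 6)),
                        muscle_labels=labels, stage=stage)


def write_keypoints_csv(path: str | Path, kp: KeypointTrajectories) -> None:
    df = pd.DataFrame(kp.displacements.T, columns=list(kp.point_labels))
    df.insert(0, "time_s", kp.times())
    df.to_csv(path, index=False)


def read_keypoints_csv(path: str | Path) -> KeypointTrajectories:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else FS_VIDEO
    labels = tuple(c for c in df.columns if c != "time_s")
    return KeypointTrajectories(df[list(labels)].to_numpy().T, fs=float(round(fs, 6)),
                                point_labels=labels)


def write_structure_json(path: str | Path, structure: TrialStructure) -> None:
    payload = [
        {"trial": s.trial, "repetition": s.repetition, "label": s.label,
         "start_s": s.start_s, "end_s": s.end_s}
        for s in structure
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_structure_json(path: str | Path) -> TrialStructure:
    payload = json.loads(Path(path).read_text())
    return TrialStructure([
        Segment(d["trial"], d["repetition"], d["label"], d["start_s"], d["end_s"])
        for d in payload
    ])
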