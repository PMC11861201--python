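"""Seeded synthetic facial-sEMG and keypoint-displacement generator.

Emulates the two-task recording protocol the pipeline expects:

* an **expression task** — six 120 s trials (one per basic expression), each
  a cycle of 5 s neutral / 5 s expression repeated 12 times.  Ground-truth
  synergy activations are smoothed trapezoids scaled per expression, with
  log-normal repetition-to-repetition amplitude jitter; muscle envelopes
  are ``Ws_true @ c(t)``; raw-like sEMG is the envelope amplitude-modulating
  a 20-450 Hz band-limited Gaussian carrier, with additive baseline noise,
  multiplicative signal-dependent noise, and linear inter-electrode
  crosstalk.  Keypoint displacements are the skin-musculoskeletal forward
  model of the noise-free activations, recombined by a ground-truth 5x5
  coupling matrix, sampled at the 25 Hz video rate with Gaussian
  measurement noise.

* an **MVC task** — five 40 s trials (4 s neutral / 4 s action, five
  cycles), each action driving a muscle subset at the maximum envelope that
  muscle reaches anywhere in the participant's expression task, so that MVC
  normalization maps expression-task envelopes into [0, 1].

The three ground-truth synergies encode the coordination structure used
throughout: synergy 1 weights CS, LLSAN and DAO and drives anger (alone),
sadness and disgust; synergy 2 weights IF, OF, DAO and Me and drives
surprise (alone), sadness, fear and disgust; synergy 3 weights ZM and DAO
and drives happiness (alone), fear and disgust.

The carrier is scaled so that the rectified-and-2 Hz-smoothed raw signal
has the ground-truth envelope as its expected value, which makes MVC
normalization consistent between tasks.  All randomness flows from one
`numpy` generator per (master seed, participant, task), so participants are
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import (
    EMGRecording,
    EXPRESSIONS,
    KEYPOINTS,
    KeypointTrajectories,
    MUSCLES,
    NEUTRAL,
    Segment,
    TrialStructure,
)
from .keypoints import MuscleMember, SMSMParameters, SpringParams, smsm_forward
from .preprocess import BANDPASS_HZ, FILTER_ORDER, video_tick_indices

TRAPEZOID_RISE_S = 0.5  # ramp time; the 1 s transition trim removes it fully

#: muscle subsets driven by each of the five MVC actions (eyebrow elevation,
#: furrowing + nose elevation, eyelid closure, mouth-corner elevation,
#: mouth-corner depression)
MVC_ACTIONS = (("IF", "OF"), ("CS", "LLSAN"), ("IF", "CS"), ("ZM",), ("DAO", "Me"))


def default_synergy_matrix() -> np.ndarray:
    """7x3 ground-truth synergy matrix, unit-norm columns."""
    w = {
        "IF": (0.0, 1.0, 0.0),
        "OF": (0.0, 0.9, 0.0),
        "CS": (1.0, 0.0, 0.0),
        "LLSAN": (0.8, 0.0, 0.0),
        "ZM": (0.0, 0.0, 1.0),
        "DAO": (0.25, 0.1, 0.7),
        "Me": (0.0, 0.6, 0.0),
    }
    Ws = np.array([w[m] for m in MUSCLES], dtype=float)
    return Ws / np.linalg.norm(Ws, axis=0)


def default_activation_map() -> dict[str, np.ndarray]:
    """Mean synergy amplitudes (fraction of MVC) per expression."""
    amp = {
        NEUTRAL: (0.0, 0.0, 0.0),
        "anger": (0.6, 0.0, 0.0),
        "surprise": (0.0, 0.6, 0.0),
        "happiness": (0.0, 0.0, 0.6),
        "sadness": (0.45, 0.45, 0.0),
        "fear": (0.0, 0.45, 0.45),
        "disgust": (0.4, 0.4, 0.4),
    }
    return {k: np.array(v, dtype=float) for k, v in amp.items()}


def default_smsm_parameters() -> SMSMParameters:
    """Ground-truth spring systems; l0 = 0 so the neutral pose is at rest."""
    singles = {
        "outer_eyebrow": SpringParams(10.0, 20.0, 0.0, 1.0),
        "nose": SpringParams(10.0, 20.0, 0.0, 0.8),
        "chin": SpringParams(10.0, 20.0, 0.0, 0.7),
    }
    doubles = {
        # agonist pulls positive, antagonist negative along the motion axis
        "mouth_corner": (MuscleMember(10.0, 20.0, 0.0, 1.0, 1.0, 1.0),
                         MuscleMember(10.0, 20.0, 0.0, -0.6, 1.0, 0.8)),
        "inner_eyebrow": (MuscleMember(10.0, 20.0, 0.0, 0.9, 1.0, 1.0),
                          MuscleMember(10.0, 20.0, 0.0, -0.5, 1.0, 0.8)),
    }
    return SMSMParameters(singles=singles, doubles=doubles)


def default_coupling() -> np.ndarray:
    """Cross-keypoint skin-coupling matrix (rows/cols in keypoint order)."""
    return np.array([
        [1.00, 0.25, 0.00, 0.00, 0.00],   # inner eyebrow <- outer eyebrow
        [0.25, 1.00, 0.10, 0.00, 0.00],   # outer eyebrow
        [0.00, 0.10, 1.00, 0.15, 0.00],   # nose
        [0.00, 0.00, 0.15, 1.00, 0.10],   # mouth corner
        [0.00, 0.00, 0.00, 0.10, 1.00],   # chin
    ])


@dataclass
class NoiseConfig:
    baseline_sd: float = 0.02           # fraction of the participant's mean MVC
    signal_dependent_coeff: float = 0.1  # multiplicative envelope jitter
    crosstalk_fraction: float = 0.02     # linear inter-electrode mixing
    keypoint_noise_sd: float = 0.005     # displacement units

    def __post_init__(self):
        for name in ("baseline_sd", "signal_dependent_coeff",
                     "crosstalk_fraction", "keypoint_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise magnitude {name} must be >= 0")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_participants: int = 10
    n_repetitions: int = 12
    fs_emg: float = 1024.0
    fs_video: float = 25.0
    expression_duration: float = 5.0
    neutral_duration: float = 5.0
    mvc_action_duration: float = 4.0
    mvc_neutral_duration: float = 4.0
    mvc_cycles: int = 5
    amplitude_jitter_sigma: float = 0.15
    synergy_matrix_true: np.ndarray = field(default_factory=default_synergy_matrix)
    expression_activation_map: dict[str, np.ndarray] = field(
        default_factory=default_activation_map)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    smsm_params_true: SMSMParameters = field(default_factory=default_smsm_parameters)
    coupling_true: np.ndarray = field(default_factory=default_coupling)

    def __post_init__(self):
        for name in ("fs_emg", "fs_video", "expression_duration",
                     "neutral_duration", "mvc_action_duration",
                     "mvc_neutral_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"configuration error: {name} must be positive")
        if self.n_participants < 1 or self.n_repetitions < 1 or self.mvc_cycles < 1:
            raise ValueError("configuration error: counts must be >= 1")
        Ws = np.asarray(self.synergy_matrix_true, dtype=float)
        if Ws.shape != (len(MUSCLES), 3) or np.any(Ws < 0):
            raise ValueError("synergy_matrix_true must be a non-negative 7x3 matrix")
        if not np.allclose(np.linalg.norm(Ws, axis=0), 1.0, atol=1e-8):
            raise ValueError("synergy_matrix_true columns must have unit norm")
        self.synergy_matrix_true = Ws
        amap = self.expression_activation_map
        if set(amap) != set((NEUTRAL,) + EXPRESSIONS):
            raise ValueError("activation map must cover neutral + 6 expressions")
        if np.any(np.asarray(amap[NEUTRAL]) != 0):
            raise ValueError("neutral must map to the zero activation vector")


@dataclass
class GroundTruth:
    """Generator sidecar: everything the pipeline tries to recover."""

    Ws_true: np.ndarray
    C_true: np.ndarray                  # 3 x T synergy activations at fs_emg
    mvc_true: np.ndarray                # per-muscle max envelope, mV
    smsm_params: SMSMParameters
    coupling: np.ndarray
    keypoints_noiseless: np.ndarray     # 5 x T_video
    fs_emg: float

    @property
    def muscle_envelope(self) -> np.ndarray:
        return self.Ws_true @ self.C_true

    @property
    def activation(self) -> np.ndarray:
        """Envelope as fraction of MVC (the SMSM input scale)."""
        return self.muscle_envelope / self.mvc_true[:, None]


@dataclass
class ExpressionTaskData:
    emg: EMGRecording
    keypoints: KeypointTrajectories
    structure: TrialStructure
    truth: GroundTruth


@dataclass
class MVCTaskData:
    emg: EMGRecording
    structure: TrialStructure
    mvc_true: np.ndarray


def _rng(config: GeneratorConfig, participant: int, stream: int) -> np.random.Generator:
    # fixed (seed, participant, stream) key: participants are independently
    # reproducible and tasks draw from disjoint streams
    return np.random.default_rng([config.seed, participant, stream])


def _check_participant(config: GeneratorConfig, participant: int) -> None:
    if not 0 <= participant < config.n_participants:
        raise ValueError(f"participant {participant} outside 0..{config.n_participants - 1}")


def _trapezoid(n: int, fs: float, rise_s: float = TRAPEZOID_RISE_S) -> np.ndarray:
    """Smoothed trapezoid on n samples: cosine ramps of rise_s at both ends."""
    t = np.arange(n) / fs
    dur = n / fs
    rise = min(rise_s, dur / 2)
    env = np.ones(n)
    up = t < rise
    env[up] = 0.5 * (1 - np.cos(np.pi * t[up] / rise))
    down = t > dur - rise
    env[down] = 0.5 * (1 - np.cos(np.pi * (dur - t[down]) / rise))
    return env


def _expression_ground_activations(config: GeneratorConfig, participant: int):
    """Trapezoidal synergy activations + trial structure for one participant."""
    rng = _rng(config, participant, 0)
    fs = config.fs_emg
    n_neu = int(round(config.neutral_duration * fs))
    n_exp = int(round(config.expression_duration * fs))
    cycle = n_neu + n_exp
    per_trial = cycle * config.n_repetitions
    T = per_trial * len(EXPRESSIONS)
    C = np.zeros((3, T))
    segments = []
    shape = _trapezoid(n_exp, fs)
    sigma = config.amplitude_jitter_sigma
    for trial, expr in enumerate(EXPRESSIONS):
        amp = np.asarray(config.expression_activation_map[expr], dtype=float)
        for rep in range(config.n_repetitions):
            start = trial * per_trial + rep * cycle
            # unit-mean log-normal amplitude jitter, one draw per synergy
            jitter = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=3)) \
                if sigma > 0 else np.ones(3)
            C[:, start + n_neu:start + cycle] = \
                (amp * jitter)[:, None] * shape[None, :]
            t0 = start / fs
            segments.append(Segment(trial, rep, NEUTRAL, t0, t0 + config.neutral_duration))
            segments.append(Segment(trial, rep, expr, t0 + config.neutral_duration,
                                    t0 + config.neutral_duration + config.expression_duration))
    return C, TrialStructure(segments), rng


def _band_limited_noise(rng, shape, fs, band=BANDPASS_HZ):
    white = rng.standard_normal(shape)
    sos = sps.butter(FILTER_ORDER, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _slow_noise(rng, shape, fs, cutoff=2.0):
    white = rng.standard_normal(shape)
    sos = sps.butter(FILTER_ORDER, cutoff, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _synthesize_raw(env: np.ndarray, mvc_mean: float, noise: NoiseConfig,
                    fs: float, rng) -> np.ndarray:
    """Amplitude-modulated band-limited carrier + baseline + crosstalk.

    The carrier is scaled by sqrt(pi/2) so that E[|carrier|] = 1 and the
    smoothed rectified raw signal tracks ``env`` directly.
    """
    scale = np.sqrt(np.pi / 2)
    amp = env.copy()
    if noise.signal_dependent_coeff > 0:
        xi = _slow_noise(rng, env.shape, fs)
        amp = np.clip(env * (1.0 + noise.signal_dependent_coeff * xi), 0.0, None)
    raw = np.zeros_like(env)
    if np.any(amp > 0):
        carrier = _band_limited_noise(rng, env.shape, fs) * scale
        raw = amp * carrier
    if noise.baseline_sd > 0:
        base = noise.baseline_sd * mvc_mean
        raw = raw + base * _band_limited_noise(rng, env.shape, fs) * scale
    cf = noise.crosstalk_fraction
    if cf > 0:
        n = env.shape[0]
        A = (1 - cf) * np.eye(n) + (cf / (n - 1)) * (np.ones((n, n)) - np.eye(n))
        raw = A @ raw
    return raw


def generate_expression_task(config: GeneratorConfig,
                             participant: int) -> ExpressionTaskData:
    """Six single-expression trials (concatenated) for one participant."""
    _check_participant(config, participant)
    C, structure, rng = _expression_ground_activations(config, participant)
    Ws = config.synergy_matrix_true
    env = Ws @ C
    mvc_true = env.max(axis=1)
    if np.any(mvc_true <= 0):
        silent = [m for m, v in zip(MUSCLES, mvc_true) if v <= 0]
        raise ValueError(f"configuration error: muscle(s) never recruited: {silent}")

    raw = _synthesize_raw(env, float(mvc_true.mean()), config.noise,
                          config.fs_emg, rng)
    emg = EMGRecording(raw, fs=config.fs_emg, stage="raw")

    # keypoints from the noise-free normalized activations at video ticks
    u = env / mvc_true[:, None]
    ticks = video_tick_indices(config.fs_emg, env.shape[1], config.fs_video)
    d_local = smsm_forward(config.smsm_params_true, u[:, ticks])
    d_clean = np.asarray(config.coupling_true, dtype=float) @ d_local
    disp = d_clean.copy()
    if config.noise.keypoint_noise_sd > 0:
        disp = disp + config.noise.keypoint_noise_sd * \
            rng.standard_normal(disp.shape)
    kp = KeypointTrajectories(disp, fs=config.fs_video)

    truth = GroundTruth(Ws_true=Ws.copy(), C_true=C, mvc_true=mvc_true,
                        smsm_params=config.smsm_params_true,
                        coupling=np.asarray(config.coupling_true, dtype=float),
                        keypoints_noiseless=d_clean, fs_emg=config.fs_emg)
    return ExpressionTaskData(emg, kp, structure, truth)


def generate_mvc_task(config: GeneratorConfig, participant: int) -> MVCTaskData:
    """Five MVC trials driving muscle subsets at the expression-task maxima."""
    _check_participant(config, participant)
    C, _, _ = _expression_ground_activations(config, participant)
    mvc_true = (config.synergy_matrix_true @ C).max(axis=1)

    rng = _rng(config, participant, 1)
    fs = config.fs_emg
    n_neu = int(round(config.mvc_neutral_duration * fs))
    n_act = int(round(config.mvc_action_duration * fs))
    cycle = n_neu + n_act
    per_trial = cycle * config.mvc_cycles
    T = per_trial * len(MVC_ACTIONS)
    env = np.zeros((len(MUSCLES), T))
    segments = []
    shape = _trapezoid(n_act, fs)
    for trial, action in enumerate(MVC_ACTIONS):
        rows = [MUSCLES.index(m) for m in action]
        for rep in range(config.mvc_cycles):
            start = trial * per_trial + rep * cycle
            env[rows, start + n_neu:start + cycle] = \
                mvc_true[rows, None] * shape[None, :]
            t0 = start / fs
            segments.append(Segment(trial, rep, NEUTRAL, t0,
                                    t0 + config.mvc_neutral_duration))
    raw = _synthesize_raw(env, float(mvc_true.mean()), config.noise, fs, rng)
    return MVCTaskData(EMGRecording(raw, fs=fs, stage="raw"),
                       TrialStructure(segments), mvc_true)
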