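"""End-to-end seeded experiment runner.

Reproduces the two analyses on synthetic data: (1) facial-expression
recognition from synergy-activation features versus per-muscle envelope
features, and (2) keypoint-displacement estimation comparing the SMSM, LRM
and hybrid SMSM-LRM models, including the across-participant ANOVA and
Tukey HSD comparison.  A single master seed fans out into named sub-seeds
(generation, trial reordering, NMF restarts, train/test split, forest,
Adam initialization) so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, keypoints, preprocess, synergy, synthetic
from .core import KEYPOINTS, MUSCLES

logger = logging.getLogger("myoface")

_SEED_TAGS = {"reorder": 101, "nmf": 211, "split": 307, "forest": 401, "adam": 503}


def sub_seed(master: int, tag: str, extra: int = 0) -> int:
    """Named, collision-resistant sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(master), _SEED_TAGS[tag], int(extra)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentConfig:
    seed: int = 0
    generator: synthetic.GeneratorConfig | None = None
    synergy_threshold: float = 90.0
    synergy_restarts: int = 10
    forced_rank: int | None = None       # None: use the VAF-selected rank
    window: int = classify.WINDOW_SAMPLES
    step: int | None = None
    n_trees: int = 100
    classifier_cv_folds: int = 5
    n_train_trials: int = 10
    keypoint_model_kinds: tuple[str, ...] = keypoints.MODEL_KINDS
    keypoint_epochs: int = 18000
    keypoint_folds: int = 5
    keypoint_lr: float = 1e-3

    def __post_init__(self):
        if self.generator is None:
            self.generator = synthetic.GeneratorConfig(seed=self.seed)

    def to_manifest(self) -> dict:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return {"seed": self.seed,
                "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
                "config": json.loads(blob)}


@dataclass
class ParticipantData:
    """Preprocessed, reordered and trimmed data for one participant."""

    index: int
    trials: list[preprocess.ReorderedTrial]   # envelope at 1024 Hz + keypoints
    trials_25hz: list[np.ndarray]             # downsampled envelope, 7 x T
    mvc: object
    truth: synthetic.GroundTruth
    decomposition: synergy.SynergyDecomposition | None = None
    vaf_curve: synergy.VafCurve | None = None
    selected_rank: int | None = None


def prepare_participant(cfg: ExperimentConfig, participant: int,
                        with_synergies: bool = True) -> ParticipantData:
    """Generate, preprocess, reorder, trim and (optionally) decompose."""
    gen = cfg.generator
    expr = synthetic.generate_expression_task(gen, participant)
    mvc_task = synthetic.generate_mvc_task(gen, participant)

    mvc_profile = preprocess.compute_mvc(preprocess.bandpass_rectify(mvc_task.emg))
    env = preprocess.normalize_and_envelope(
        preprocess.bandpass_rectify(expr.emg), mvc_profile)

    reordered = preprocess.reorder_trials(
        env, expr.structure, sub_seed(cfg.seed, "reorder", participant),
        keypoints=expr.keypoints)
    trimmed = [preprocess.trim_reordered(t) for t in reordered]
    trials_25 = [preprocess.downsample_to_video(t.emg).samples for t in trimmed]

    data = ParticipantData(participant, trimmed, trials_25, mvc_profile, expr.truth)
    if with_synergies:
        U25 = np.concatenate(trials_25, axis=1)
        s_star, curve = synergy.select_rank(
            U25, threshold=cfg.synergy_threshold,
            n_restarts=cfg.synergy_restarts,
            seed=sub_seed(cfg.seed, "nmf", participant))
        rank = cfg.forced_rank or s_star
        data.decomposition = synergy.fit_nmf(
            U25, rank, n_restarts=cfg.synergy_restarts,
            seed=sub_seed(cfg.seed, "nmf", participant) + rank)
        data.vaf_curve = curve
        data.selected_rank = s_star
    return data


@dataclass
class FERResult:
    report_synergy: classify.ClassifierReport
    report_semg: classify.ClassifierReport
    cv_accuracy: dict[str, float | None]
    split: dict[int, tuple[tuple[int, ...], tuple[int, ...]]]
    participants: list[ParticipantData] = field(repr=False, default_factory=list)


def _participant_feature_tables(cfg: ExperimentConfig, data: ParticipantData,
                                rank: int) -> tuple[list, list]:
    """Per-trial synergy-mode and sEMG-mode feature tables (1024 Hz)."""
    Ws = data.decomposition.Ws
    if data.decomposition.rank != rank:
        raise ValueError("participant decomposition rank differs from pooled rank")
    syn_tables, emg_tables = [], []
    syn_names = [f"syn{i + 1}" for i in range(rank)]
    for trial in data.trials:
        C = synergy.activations_for(Ws, trial.emg.samples)
        syn_tables.append(classify.sliding_features(
            C, trial.structure, trial.emg.fs, syn_names,
            window=cfg.window, step=cfg.step))
        emg_tables.append(classify.sliding_features(
            trial.emg.samples, trial.structure, trial.emg.fs, list(MUSCLES),
            window=cfg.window, step=cfg.step))
    return syn_tables, emg_tables


def run_fer_experiment(cfg: ExperimentConfig,
                       participants: list[ParticipantData] | None = None,
                       ) -> FERResult:
    """Full recognition pipeline; returns pooled window-level reports."""
    t0 = time.time()
    if participants is None:
        participants = [prepare_participant(cfg, p)
                        for p in range(cfg.generator.n_participants)]
    ranks = {d.selected_rank for d in participants}
    rank = cfg.forced_rank or max(ranks)
    for d in participants:
        if d.decomposition.rank != rank:
            d.decomposition = synergy.fit_nmf(
                np.concatenate(d.trials_25hz, axis=1), rank,
                n_restarts=cfg.synergy_restarts,
                seed=sub_seed(cfg.seed, "nmf", d.index) + rank)
    logger.info("synergy ranks selected: %s (pooled rank %d)", sorted(ranks), rank)

    # column j must denote the same synergy for every participant before
    # activation features are pooled; align to the first participant's basis
    ref_Ws = participants[0].decomposition.Ws
    for d in participants[1:]:
        d.decomposition = synergy.align_to_reference(d.decomposition, ref_Ws)

    n_trials = len(participants[0].trials)
    split = classify.split_train_test(
        [d.index for d in participants], n_trials=n_trials,
        n_train=cfg.n_train_trials, seed=sub_seed(cfg.seed, "split"))

    pools = {"synergy": {"train": [], "test": []},
             "semg": {"train": [], "test": []}}
    for d in participants:
        syn_tables, emg_tables = _participant_feature_tables(cfg, d, rank)
        train_idx, test_idx = split[d.index]
        for mode, tables in (("synergy", syn_tables), ("semg", emg_tables)):
            pools[mode]["train"] += [tables[i] for i in train_idx]
            pools[mode]["test"] += [tables[i] for i in test_idx]

    reports, cv = {}, {}
    for mode in ("synergy", "semg"):
        train = classify.concat_tables(pools[mode]["train"])
        test = classify.concat_tables(pools[mode]["test"])
        clf = classify.train_classifier(
            train, n_trees=cfg.n_trees, cv_folds=cfg.classifier_cv_folds,
            seed=sub_seed(cfg.seed, "forest"))
        reports[mode] = classify.evaluate_classifier(clf, test)
        cv[mode] = clf.cv_accuracy
        logger.info("%s-mode test accuracy %.2f%% (%.1f s elapsed)",
                    mode, reports[mode].accuracy, time.time() - t0)
    return FERResult(reports["synergy"], reports["semg"], cv, split, participants)


@dataclass
class KeypointResult:
    metrics: pd.DataFrame          # rows: participant x model; NRMSE and R2
    fits: dict[tuple[int, str], keypoints.FitResult]
    comparison_nrmse: keypoints.ModelComparison | None
    comparison_r2: keypoints.ModelComparison | None


def run_keypoint_experiment(cfg: ExperimentConfig,
                            participants: list[ParticipantData] | None = None,
                            ) -> KeypointResult:
    """Fit SMSM / LRM / SMSM-LRM per participant and compare test metrics."""
    t0 = time.time()
    if participants is None:
        participants = [prepare_participant(cfg, p, with_synergies=False)
                        for p in range(cfg.generator.n_participants)]
    n_trials = len(participants[0].trials)
    split = classify.split_train_test(
        [d.index for d in participants], n_trials=n_trials,
        n_train=cfg.n_train_trials, seed=sub_seed(cfg.seed, "split"))

    rows = []
    fits = {}
    for d in participants:
        train_idx, test_idx = split[d.index]
        U_trials = d.trials_25hz
        Y_trials = [t.keypoints.displacements for t in d.trials]
        U_train = [U_trials[i] for i in train_idx]
        Y_train = [Y_trials[i] for i in train_idx]
        U_test = np.concatenate([U_trials[i] for i in test_idx], axis=1)
        Y_test = np.concatenate([Y_trials[i] for i in test_idx], axis=1)
        for kind in cfg.keypoint_model_kinds:
            fit = keypoints.fit_model(
                kind, U_train, Y_train, epochs=cfg.keypoint_epochs,
                folds=cfg.keypoint_folds, lr=cfg.keypoint_lr,
                seed=sub_seed(cfg.seed, "adam",
                              1000 * d.index + keypoints.MODEL_KINDS.index(kind)))
            m = keypoints.regression_metrics(Y_test, fit.predict(U_test))
            fits[(d.index, kind)] = fit
            rows.append({"participant": d.index, "model": kind,
                         "nrmse": m["mean_nrmse"], "r2": m["mean_r2"],
                         **{f"nrmse_{k}": v for k, v in
                            zip(KEYPOINTS, m["nrmse_per_keypoint"])},
                         **{f"r2_{k}": v for k, v in
                            zip(KEYPOINTS, m["r2_per_keypoint"])}})
            logger.info("participant %d %s: NRMSE %.4f R2 %.2f (%.1f s)",
                        d.index, kind, m["mean_nrmse"], m["mean_r2"],
                        time.time() - t0)
    metrics = pd.DataFrame(rows)

    cmp_nrmse = cmp_r2 = None
    kinds = list(cfg.keypoint_model_kinds)
    if len(kinds) >= 2 and metrics["participant"].nunique() >= 2:
        groups_n = {k: metrics.loc[metrics.model == k, "nrmse"].to_numpy()
                    for k in kinds}
        groups_r = {k: metrics.loc[metrics.model == k, "r2"].to_numpy()
                    for k in kinds}
        cmp_nrmse = keypoints.compare_models(groups_n)
        cmp_r2 = keypoints.compare_models(groups_r)
    return KeypointResult(metrics, fits, cmp_nrmse, cmp_r2)


def write_manifest(out_dir: str | Path, cfg: ExperimentConfig) -> Path:
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = cfg.to_manifest()
    manifest["package_version"] = __version__
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
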