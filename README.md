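# myoface

Facial-expression recognition and facial-keypoint displacement estimation
from multichannel facial surface EMG (sEMG).

Most facial-expression systems work from video. Recording the *muscles*
instead — seven facial muscle regions (inner/outer frontalis, corrugator
supercilii, levator labii superioris alaeque nasi, zygomaticus major,
depressor anguli oris, mentalis) at 1024 Hz — gives direct access to the
motor commands behind an expression. `myoface` implements the two analyses
such recordings support, for researchers in biosignal processing,
muscle-synergy analysis and expressive robotics:

1. **Recognition.** sEMG envelopes (20–450 Hz band-pass, rectification,
   MVC normalization, 2 Hz low-pass) are factorized by non-negative matrix
   factorization into muscle synergies, `U ≈ Ws·C`, with the rank chosen
   as the smallest `s` whose variance accounted for,
   `VAF = 100·(1 − ‖U − Ws C‖²_F/‖U‖²_F)`, reaches 90%.  Sliding-window
   features (RMS, VAR, MAV, IEMG; R = 125 samples, 40 ms step) of either
   the synergy activations or the raw envelopes feed a 100-tree random
   forest that classifies windows into neutral + six basic expressions
   (anger, disgust, fear, happiness, sadness, surprise).

2. **Displacement estimation.** Each of five facial keypoints (inner and
   outer eyebrow, nose, mouth corner, chin) is modelled as the spring
   equilibrium between skin (stiffness `K_H = 100 N/m`) and one or two
   muscles with activation-dependent stiffness `k₀ + k₁u` and rest length
   `l₀ + l₁u`, giving e.g. for a single-muscle system

       Δl = (k₀ + k₁u)(l₀ + l₁u) / (K_H + k₀ + k₁u).

   This skin-musculoskeletal model (SMSM), a plain linear regression
   (LRM, `ΔL = W_lrm U`), and their hybrid (SMSM-LRM,
   `ΔL = W·Δl_SMSM`, a fitted 5×5 recombination that captures skin
   coupling between keypoints) are fitted by Adam on the mean squared
   displacement error with 5-fold cross-validation, and compared by
   per-keypoint R² and range-normalized RMSE with ANOVA + Tukey HSD.

Because such human recordings are rarely shareable, the package includes a
seeded synthetic-data generator that emulates the full recording protocol
(MVC task + expression task, amplitude-modulated band-limited carriers,
signal-dependent noise, crosstalk, keypoint measurement noise) from three
ground-truth synergies and a ground-truth spring model. See
`docs/methods.md` for the model details and what the generator does and
does not emulate.

## Worked example

Using the command-line interface on a small synthetic cohort (2
participants, 6 repetitions per expression):

```
$ cat cfg.json
{"generator": {"n_participants": 2, "n_repetitions": 6},
 "n_train_trials": 4, "classifier_cv_folds": 0,
 "keypoint_folds": 4, "keypoint_epochs": 2500}

$ myoface synergies --config cfg.json --seed 0 --out out
participant 0: rank 3, VAF 99.43%

$ myoface eval-fer --config cfg.json --seed 0 --out out
synergy-mode accuracy: 100.00%
sEMG-mode accuracy:    100.00%

$ myoface fit-keypoints --config cfg.json --seed 0 --out out
SMSM: NRMSE 0.0625  R2 93.69
LRM: NRMSE 0.0521  R2 95.13
SMSM-LRM: NRMSE 0.0485  R2 95.75
```

Reading the output: the VAF rule selects 3 synergies (the generator's
ground-truth rank) and rank 3 explains 99.4% of the envelope variance; at
this small scale both classifiers separate the seven classes perfectly on
the held-out trials; and the hybrid SMSM-LRM predicts held-out keypoint
displacements with the lowest normalized RMSE, ahead of both of its
components — the SMSM alone cannot represent the skin coupling between
keypoints, the LRM alone cannot represent the spring nonlinearity.
`out/` then holds the synergy matrix and activations, the classification
reports and confusion matrices, per-model metrics (CSV/JSON) and a
manifest (config hash + seed) that reproduces the run exactly.

The same pipeline is available as a library:

```python
import myoface as mf

cfg = mf.ExperimentConfig(seed=0)          # 10 participants, default noise
fer = mf.run_fer_experiment(cfg)
print(fer.report_synergy.accuracy, fer.report_semg.accuracy)
kp = mf.run_keypoint_experiment(cfg)
print(kp.metrics.groupby("model")[["nrmse", "r2"]].mean())
```

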