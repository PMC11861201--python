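# Methods

`myoface` implements two coupled analyses of multichannel facial surface
EMG (sEMG): recognition of the six basic facial expressions from muscle
synergies, and estimation of facial-keypoint displacements through a
skin-musculoskeletal spring model.  Because the human recordings such a
pipeline is designed for are rarely shareable, the package ships a
first-class synthetic-data generator that reproduces the statistical
structure the pipeline assumes; every stage is tested against that
generator's ground truth.

## Recording model

Seven facial muscle regions are recorded at 1024 Hz — inner frontalis
(IF), outer frontalis (OF), corrugator supercilii (CS), levator labii
superioris alaeque nasi (LLSAN), zygomaticus major (ZM), depressor anguli
oris (DAO), and mentalis (Me) — together with the 25 Hz video-tracked 1-D
displacements of five keypoints: inner eyebrow, outer eyebrow, nose
(superior end of the nasolabial fold), mouth corner, and chin.  Two tasks
are modelled: a maximum-voluntary-contraction (MVC) task of five 40 s
trials (five cycles of 4 s neutral / 4 s action each), and an expression
task of six 120 s trials, each cycling 5 s neutral / 5 s of one expression
twelve times.

## Preprocessing

Raw sEMG is band-pass filtered 20–450 Hz, full-wave rectified, divided per
muscle by its MVC value, and low-pass filtered at 2 Hz to form the
activation envelope.  Both filters are 4th-order Butterworth designs
applied forward-and-backward (`sosfiltfilt`).  Design choices:

* **Zero-phase filtering.** The filter family and phase convention are a
  package choice; zero-phase filtering avoids group delay between the sEMG
  envelope and the video-tracked keypoints, which matters for the
  regression models.  The zero-phase low-pass can undershoot below zero;
  the envelope is clipped at 0 to preserve the non-negativity NMF needs.
* **MVC value = maximum of the 2 Hz-smoothed rectified MVC recording**,
  per muscle — robust to single-sample spikes.  Note that for an
  amplitude-modulated stochastic carrier the maximum of the smoothed
  rectified signal is a max statistic that sits reproducibly ~10–15% above
  the underlying envelope peak; the bias is common to the MVC and
  expression tasks and cancels under normalization, and every evaluation
  metric downstream (VAF, accuracy, R², NRMSE) is scale-free.
* **Downsampling to the 25 Hz video rate** selects the sample nearest each
  40 ms tick (no decimation filter): the 2 Hz envelope is band-limited far
  below the 12.5 Hz output Nyquist frequency, so nothing aliases.
* **Transition trimming.** 1 s of data adjacent to every label transition
  (and the recording edges of spliced trials) is discarded from both the
  sEMG and keypoint streams — in real recordings these samples carry
  electrode-friction artifacts; in the generator they contain the envelope
  ramps.  Segment times are half-open `[start, end)` intervals in seconds.
* **Reordered trials.** The six single-expression trials are recombined
  into twelve reordered trials: for each repetition slot, one expression
  segment (with its preceding neutral context) is drawn without
  replacement from each source trial and the six draws are shuffled.  Each
  reordered trial holds 6 × (5 s neutral + 5 s expression) = 60 s, and
  after trimming 36 s = 900 samples at 25 Hz.

## Muscle synergies

The envelope matrix `U` (muscles × time) is factorized as `U ≈ Ws·C` with
non-negative `Ws` (muscles × s) and `C` (s × time), minimizing the
Frobenius loss with scikit-learn's coordinate-descent NMF over 10 random
restarts.  Model order is the smallest `s` whose variance accounted for,

    VAF = 100·(1 − ‖U − Ws·C‖²_F / ‖U‖²_F),

reaches 90% — the standard rule in the synergy literature.  The VAF is the
global Frobenius form (not per-muscle averaged), the dominant convention.
Columns of `Ws` are normalized to unit Euclidean norm with the magnitude
moved into `C`, and sorted by descending activation energy; comparisons
across datasets always go through optimal column matching under cosine
similarity (exhaustive over permutations — rank ≤ 7 keeps this exact).

Two numerical choices are worth flagging:

* **Extraction rate.** Synergies are extracted from the envelopes at the
  25 Hz downsampled rate.  The 2 Hz envelope is fully represented there,
  so the factorization is statistically identical to one at 1024 Hz while
  being ~40× cheaper — which is what makes the rank scan (s = 1..7, 10
  restarts each) affordable per participant.
* **Activation coefficients at 1024 Hz** (needed for classification
  features) are recovered against the fixed `Ws` by exact per-sample
  non-negative least squares, vectorized by enumerating active sets and
  keeping the best primal-feasible candidate.  This is exact for the ranks
  involved and is verified against `scipy.optimize.nnls` in the tests.

Per-expression activation clusters are summarized by the centroid and the
3-D convex hull (`scipy.spatial.ConvexHull`) of the activation points;
fewer than four non-coplanar points yields a flagged zero-volume hull.

## Expression classification

Sliding windows of R = 125 samples with a 40 ms step (one video frame) are
cut from either the synergy activations (`s`×4 features) or the envelopes
(7×4 features); windows never straddle a segment boundary and inherit the
segment label.  Per window and channel: RMS, variance (1/R normalization),
mean absolute value, and integrated EMG (the sum of absolute values, so
IEMG = R·MAV holds exactly).  R is specified in samples; at 1024 Hz the
default R = 125 spans ~122 ms (the nominal window length in this protocol
family is 150 ms; both are configurable).

Because the NMF column order is arbitrary per participant, pooling
synergy-activation features across participants first aligns every
participant's synergy basis to a reference participant through the
optimal cosine pairing — column `j` then denotes the same synergy for
everyone.

A random forest with 100 trees (scikit-learn defaults otherwise,
unweighted classes) classifies windows into neutral + six expressions.
Training pools 10 of the 12 reordered trials per participant across all
participants; the remaining 2 per participant form the test set.  Metrics
are window-level: overall and per-class accuracy, precision/recall/F1,
one-vs-rest ROC/AUC from class probabilities, and the confusion matrix
(true rows × predicted columns).  Five-fold cross-validated training
accuracy can be reported alongside; it does not affect the final model,
which is refit on all training rows.

## Keypoint displacement models

Each keypoint is modelled as the equilibrium of a linear skin spring
(stiffness `KH = 100 N/m`, fixed, not fitted) against one or two muscle
springs with activation-dependent stiffness `k0 + k1·u` and rest-length
offset `l0 + l1·u` (the Mykin muscle model).  Single-muscle systems
(OF→outer eyebrow, LLSAN→nose, Me→chin):

    Δl = (k0 + k1·u)(l0 + l1·u) / (KH + k0 + k1·u)

Double-muscle systems (ZM+DAO→mouth corner, IF+CS→inner eyebrow), with
projection coefficients `a_i` and geometry coefficients `λ_i`:

    Δl = Σ_i a_i(k0_i + k1_i·u_i)(l0_i + l1_i·u_i)
         / (KH + Σ_i a_i·λ_i(k0_i + k1_i·u_i))

The LRM is the ordinary least-squares map `ΔL = W_lrm·U` (5×7); the hybrid
SMSM-LRM recombines the five SMSM outputs with a fitted 5×5 matrix,
`ΔL = W·Δl_SMSM`, capturing skin coupling between keypoints that the local
systems ignore.

Displacements are 1-D signed projections onto each keypoint's dominant
motion axis (elevation-positive for eyebrows/nose/chin, ZM-pull-positive
for the mouth corner); `a_i` and `λ_i` may be negative (antagonists).
Displacement units are arbitrary — harmless, because every evaluation
metric is scale-free, and the N/m-vs-pixel mismatch is absorbed by the
fitted `l0, l1`.

**Fitting.** Spring parameters (and `W` for the hybrid) are fitted by
full-batch gradient descent with Adam (step 1e-3, default moment decays,
18 000 epochs by default) on the mean squared error over all five
keypoints jointly, with analytic gradients (verified against finite
differences).  `k0, k1` are kept positive by a soft-plus
reparameterization; `l0 = 0` at initialization so the neutral pose starts
at rest; a quadratic penalty keeps every equilibrium denominator above
1e-6·KH over the admissible activation box u ∈ [0, 1.5].  The LRM is
solved in closed form by default, with an Adam path for parity.  Training
uses 5-fold cross-validation over the 10 training trials; the fold model
with the lowest validation MSE is kept and scored on the 2 held-out
trials.  Because `(k0 + k1·u)(l0 + l1·u)` is invariant under reciprocal
rescaling of its factors, recovered spring constants are not identifiable
— all quality statements are about predictions.

**Evaluation.** Per keypoint: R² on the 0–100 scale and RMSE normalized by
that keypoint's max−min range in the true test data (per-keypoint
normalization; configurable).  Model comparison across participants uses
one-way ANOVA followed by Tukey's HSD (`scipy.stats`).

## Synthetic-data generator

The generator encodes the coordination structure the pipeline is designed
around — three ground-truth synergies with unit-norm columns:

| synergy | muscles (weights before normalization) | sole driver of | shared by |
|---|---|---|---|
| 1 | CS 1.0, LLSAN 0.8, DAO 0.5 | anger | sadness, disgust |
| 2 | IF 1.0, OF 0.9, DAO 0.4, Me 0.6 | surprise | sadness, fear, disgust |
| 3 | ZM 1.0, DAO 0.5 | happiness | fear, disgust |

Mean synergy amplitudes (fraction of MVC): single-synergy expressions 0.6;
two-synergy expressions 0.45 each; disgust 0.4 on all three; neutral 0.
Per repetition each active synergy's amplitude is jittered by a unit-mean
log-normal factor (σ = 0.15), a realistic trial-to-trial variability for
voluntary facial contractions.

Synergy activations are smoothed trapezoids with 0.5 s cosine ramps, so
the 1 s transition trim removes exactly the non-stationary part.  Raw
sEMG is synthesized as the muscle envelope (`Ws_true·c(t)`) amplitude-
modulating a 20–450 Hz band-limited Gaussian carrier scaled so the
smoothed rectified signal tracks the envelope in expectation; this
exercises the full filtering path rather than just the downstream
algebra.  Noise terms (defaults): additive baseline noise with sd = 2% of
the participant's mean MVC; multiplicative signal-dependent amplitude
noise with coefficient 0.1 (sd proportional to the envelope, as in motor
noise models); linear inter-electrode crosstalk mixing fraction 0.02; and
Gaussian keypoint measurement noise with sd 0.005 displacement units
(~2–3% of a typical keypoint range, i.e. ordinary video-tracking jitter).
The SNR was chosen so the recognition task is demanding but solvable — the
classifier is well above chance-limited and below saturation.

Keypoint displacements are the SMSM forward model of the noise-free
normalized activations, recombined by a ground-truth 5×5 coupling matrix
(identity plus 0.1–0.25 couplings between anatomically adjacent points:
the two eyebrow points, eyebrow–nose, nose–mouth, mouth–chin), sampled at
the video ticks, plus measurement noise.  Ground-truth spring parameters
use k0 = 10, k1 = 20 N/m, l0 = 0 (neutral pose at rest) and l1 of order
one with antagonist signs for DAO and CS.  The MVC task drives each
muscle subset at the maximum envelope that muscle attains anywhere in the
participant's expression task, so normalized envelopes land in [0, 1].

All randomness flows from `numpy` generators keyed by (master seed,
participant, task), so participants are independently reproducible and a
single master seed fans out to named sub-seeds for reordering, NMF
restarts, the train/test split, the forest, and Adam initialization.

**What the generator does not emulate:** electrode lift/motion artifacts
beyond white and signal-dependent noise, muscle fatigue, asymmetric
expressions, 2-D keypoint motion, viscoelastic (damped) skin dynamics, or
inter-participant anatomical variation in the synergy structure (only
amplitudes vary across participants).  Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical assumptions,
not performance on human recordings.

## Problem sizes and numerical tolerances

* The acceptance script and the heavyweight tests run the full cohort of
  10 participants with 12 repetitions (the study-scale default).  The
  classifier's cross-validated training accuracy is skipped there (the
  reported quantity is held-out test accuracy), and the Adam budget is
  2500 full-batch epochs per fold — the hybrid model's test NRMSE is flat
  beyond ~2000 epochs on this data, while the default of 18 000 remains
  for general use.  Replication checks at additional seeds keep the full
  per-participant protocol (12 reordered trials, 10/2 split, 5-fold CV)
  and shrink only the cohort: with fewer training trials the hybrid's
  extra recombination weights are not yet converged and the model
  comparison is not meaningful.
* NMF restarts use a 300-iteration budget at tolerance 1e-5; the VAF curve
  is treated as non-decreasing up to a 0.5 percentage-point solver
  tolerance.  Tests that assert exact factorizations tighten the solver
  instead of loosening the assertion.
* The preprocessed envelope carries an irreducible ~5% relative estimation
  noise from smoothing the rectified stochastic carrier; self-consistency
  checks that require error floors below that (e.g. noiseless-recovery
  fits) therefore run on the generator's clean activations.

## Known limitations

* NMF non-uniqueness: on data without near-pure activations the restart
  losses can split across distinct local optima; the generator's
  expression design (three expressions drive one synergy each) makes the
  factorization essentially separable and stable.
* The equilibrium model is static; transition dynamics between expressions
  are trimmed away, not modelled.
* The ANOVA/Tukey comparison treats per-participant means as independent
  samples, as is conventional, and degenerates (F = ∞, undefined pairwise
  p) when groups have zero within-group variance.
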