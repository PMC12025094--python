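# Methods

This note documents the modelling choices in `gaitbbs`: what each stage
computes, the parameters that matter and their defaults, what the
synthetic data generator does and does not emulate, and the decisions we
made where the design was genuinely open.

## Problem setting

A subject wears one IMU on each calf and walks for several minutes; each
node streams 3-axis acceleration and 3-axis angular velocity at 100 Hz,
giving a T×12 signal (left node's six channels first, then the right's).
A separate ~10-s standing recording provides a static baseline. The target
is the subject's Berg Balance Scale total, an integer 0–56 assigned by a
physical therapist. The pipeline regresses this total from 2-s gait
windows and aggregates window predictions per subject.

## Preprocessing

**Filtering.** 4th-order Butterworth low-pass, 20 Hz cut-off, applied
forward–backward (`sosfiltfilt`). Zero-phase filtering matters here
because a causal filter would delay the angular-velocity peak used as the
gait trigger; the two-pass application squares the magnitude response, so
the effective rolloff is 8th-order. DC passes with unit gain. Signals
shorter than 3× the filter order are rejected.

**Standardization.** Per channel, `(X − μ)/σ` with μ, σ the mean and
(population) standard deviation of the subject's static baseline. The
baseline is passed through the same filter first, so both signals see
identical conditioning. This removes sensor offsets (including gravity
projections) and makes the pipeline unit-invariant — deliberately so,
since IMU hardware varies in whether acceleration is reported in g or
m/s². A baseline channel with σ < 1e-12 is an error: a perfectly constant
"standing" channel means a dead sensor, not a quiet subject.

**Truncation and windowing.** The first and last stretch of a walking
recording (acceleration/deceleration, turning to the tester) are
unrepresentative, so `end_trim_seconds` (default 30) is dropped from both
ends, and the remainder is cut into non-overlapping windows of
`window_seconds` (default 2 s → 200 samples, comfortably longer than one
~1.6-s gait cycle). Non-overlapping stride is the default because the
canonical cohort arithmetic — 5-minute walks, 30-s trims, 120 windows per
subject, 4800 for 40 subjects — only holds without overlap; a shorter
`stride_seconds` is available for augmentation. An alternative
`trigger_plus_fixed` policy starts the usable span at the first peak of a
Z-axis angular-velocity channel (default: right node) whose height reaches
50% of the channel maximum, still trimming the end; the height rule is
ours, chosen to skip sub-threshold wobble before steady gait. Trailing
remainders shorter than one window are discarded.

**Labels.** Window labels are the subject total divided by 56 (min–max
normalization over the scale's range). This is weak labelling — every
window of a subject carries the same score — which is what makes a
40-subject study trainable at the window level. Denormalization multiplies
by 56 and snaps values within 1e-9 of an integer so integer round-trips
are exact.

## Network

Input: batch × 200 × 12 standardized windows. Output: one real-valued
normalized score per window (linear output; predictions are clipped to
[0, 1] at inference, trained with MSE — we preferred an unconstrained head
plus clipping over a sigmoid because saturated sigmoids learn slowly near
the scale ends, exactly where healthy controls sit).

* **CNN block**: Conv1D(12→32, kernel 3, 'same') → batch norm → ReLU.
* **Residual block**: route A Conv1D(32→32, kernel 3) → BN → ReLU; route B
  max pool (kernel 3, stride 1, 'same'), which preserves the input feature
  space; channel concatenation (→64); dropout 0.2. Concatenation (rather
  than addition) keeps both the expanded and the original features.
* **Attention block** on C input channels: F1 = Conv1D(C→E, kernel 3) →
  BN → ReLU with E = min(2C, 128); the block input is combined additively
  after a 1×1 projection to width E (a residual-style merge). The ECA gate
  computes a per-channel descriptor by global average pooling over time,
  convolves across the channel axis with kernel
  `k = round_to_odd(log₂(E)/τ + a/τ)` (τ=2, a=1 — the original ECA
  settings, which give k=3 at E=32 and k=5 at E=128), applies a sigmoid
  and rescales the channels. F3 = Conv1D(E→32, 1×1) followed by a global
  temporal average — the "squeeze" to one 32-vector per window. The
  temporal pooling is global, not a literal 2-D pool over time × channel,
  because per-channel gating requires a per-channel scalar descriptor.
* **Bi-LSTM head**: when fed from the attention block, the 32-vector is
  read as a length-32 sequence of scalars (the only arrangement consistent
  with placing the recurrence after the squeeze); when attention is off,
  the time-major feature map is the sequence. Forward and backward LSTMs
  have 32 hidden units each; their final states concatenate to 64, then
  dropout 0.3 and fully connected layers 64→16→1. The FC widths are ours;
  only "fully connected layers" is fixed by design.

Toggles `use_cnn` / `use_residual` / `use_attention` / `use_bilstm` build
every ablation arm from the same class; arms without a Bi-LSTM pool
features over time and feed the FC head directly.

**Implementation.** The layers, LSTMs and Adam are written in numpy with
explicit backprop (`gaitbbs.nn`); the test suite checks every layer and
the composed network against central-difference gradients. Convolutions
followed by batch norm carry no bias (BN cancels a constant shift exactly,
so such a bias would be a dead parameter — the test suite asserts every
parameter of every arm receives gradient). Weights use fan-in (He) uniform
initialisation from a seeded generator; LSTM forget-gate biases start
at 1. Batch norm uses momentum 0.1 and eps 1e-5, with running statistics
for evaluation; dropout is inverted.

## Training protocol

Adam (lr 0.001, β=0.9/0.999), MSE on normalized scores, batch 64, up to
200 epochs. Early stopping watches validation MSE with patience 20:
improvement means a strict decrease (ties count against patience, a
documented tie-break), the best epoch's weights — including batch-norm
running statistics — are restored, and when stopping triggers,
`best_epoch = stop_epoch − patience` exactly.

5-fold cross-validation rotates one fold as held-out validation/test.
`segment` split mode shuffles windows (960-window folds from a 4800-window
cohort); `subject` mode assigns whole subjects to folds. Segment mode is
the default because it matches the canonical fold arithmetic, but note its
caveat: windows of one subject appear on both sides of the split, so
segment-level metrics partly reflect subject memorisation. Subject mode is
the honest generalisation estimate; both are first-class.

Metrics are computed on the 0–56 scale (predictions denormalized and
clipped) so MAE/RMSE read directly in BBS points; per-subject scores are
unweighted means of a subject's window predictions, clipped to [0, 56].
Bland–Altman limits use differences oriented predicted − actual and the
population (÷n) standard deviation; with ~normal differences ≈95% of
subjects fall within the limits.

## Synthetic data generator

The generator provides cohorts with the structure the pipeline assumes,
not physiologic gait. Each subject's 12 channels are harmonic stacks
(4 harmonics of a ~1.6-s gait cycle, fixed per-channel amplitude templates
and phases, right node half a cycle out of phase) over a *jittered stride
phase*: successive stride periods are `1.6 s × (1 + cv·ε)` with truncated
standard-normal ε. Four degradations interpolate linearly in the score:

| parameter | at score 0 | at score 56 | emulates |
|---|---|---|---|
| stride-time CV | 0.12 | 0.02 | gait variability |
| L/R amplitude asymmetry | 0.30 | 0.02 | hemiparetic/unilateral gait |
| tremor-band (4–6 Hz) amplitude | 0.5× | 0 | parkinsonian tremor |
| overall amplitude scale | 0.6 | 1.0 | reduced, shuffling gait |

plus white noise (sd 0.05) and constant sensor offsets shared between
walking and static data (so standardization genuinely removes something).
The static baseline is offset + noise (sd 0.02). The values are our
choices of plausible magnitudes; the load-bearing property is
monotonicity, which the tests verify from the generated signals via
peak-interval statistics, side-RMS ratios and band power. Cohorts are
drawn either uniformly over a score range (default 30–56) or stratified
into the reference four-group composition (12 young HC / 8 elderly HC /
8 PD / 12 stroke with group means 55.67 / 50.63 / 47.63 / 44.50, truncated
normal, clipped and rounded).

Because the score→signal mapping is strong and low-dimensional, passing
the learning tests shows the pipeline can recover a score embedded in gait
statistics end-to-end; it does **not** show clinical-grade accuracy on
real patients, whose score-signal relationship is weaker, noisier and
confounded (walking aids, medication state, comorbidities).

## Problem sizes in the checks

The automated checks train at reduced sizes chosen for single-CPU runs:
the learning check uses 40 subjects × 60-s walks (5-s trims → 25 windows
each, 1000 windows), 5-fold CV, max 12 epochs, patience 5; the ablation
direction check (full model vs Bi-LSTM-only) uses 12-subject cohorts,
2-fold CV, max 8 epochs, over three seeds; dataset/fold arithmetic runs at
the full 40 × 5-min geometry since preprocessing is cheap. At these sizes
the full model reaches held-out MAE ≈ 1.5–2.5 BBS points against a
constant-mean baseline of ≈ 6–7.

## Known limitations

* Per-window weak labels mean the model predicts the total score only;
  individual task scores are out of reach by construction.
* No resampling: recordings must arrive at (approximately) the declared
  sample rate; timestamped files are validated, not corrected.
* The numpy trainer is single-threaded BLAS-bound; it is sized for
  hundreds-to-thousands of windows, not for large-scale studies.
* The simulator's degradations are additive and independent; real
  pathological gaits correlate them and add phenomena (freezing, festination,
  compensatory strategies) that no test here exercises.
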