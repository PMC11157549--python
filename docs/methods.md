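# Methods

## The optimizer

`gaitopt.optimizer` implements the sinh–cosh optimizer (SCHO) over a
bounded box `[lb, ub]^D` and the modified variant (MSCHO) used as the
default tuner. A population of N agents is evaluated each iteration; the
run is split by `S = floor(T / ct)` (default ct = 3.6) into an
exploration phase (iterations t ≤ S) and an exploitation phase (t > S).
Within a phase each agent picks one of two update strategies by a fair
coin from the run RNG:

* exploration 1: `a' = best ± r1·W1·a`, with
  `W1 = r3·b1·(cosh r4 + μ·sinh r4 − 1)`;
* exploration 2: `a' = best ± |ε·W2·best − a|`, ε = 0.003,
  `W2 = r6·b2`;
* exploitation 1: `a' = best ± r7·W3·a`, with
  `W3 = r9·b1·(cosh r10 + μ·sinh r10)`;
* exploitation 2: `a' = a + r11·tanh(r12)·|W2·best − a|`.

All `r` coefficients are uniform draws on [0,1], drawn **per dimension**,
so each coordinate moves independently; positions are clipped to the box
after every move. With scalar per-agent draws every coordinate moves
coherently and only diagonally-related corners of the box are reachable,
which measurably cripples exploration on flat objective plateaus — the
per-dimension form is the standard reading of per-element update
equations in this algorithm family.

Parameter defaults: μ = 0.5 (no canonical value is established; the
sensitivity is mild on the benchmarks we run, and the value is
configurable), b1 and b2 decay linearly from 2.0 and 1.5 to 0 across the
run — the simplest schedules satisfying the required monotone decrease —
and both schedules are replaceable by callables.

MSCHO adds two mechanisms:

* **quasi-reflection-based learning (QRL).** The quasi-reflected
  counterpart of x is a uniform draw between the box midpoint and x,
  per dimension. At initialization every uniform draw is replaced by its
  quasi-reflection.
* **trial abandonment.** An agent whose fitness has not strictly
  improved for `trial_limit = 2` consecutive iterations is discarded.
  Its replacement is the classical quasi-reflection pair: a fresh
  uniform draw and its quasi-reflected counterpart are both evaluated
  and the better one survives (both evaluations are counted against the
  budget). The pair form matters: the quasi-reflection alone is biased
  toward the box midpoint, whereas the uniform member of the pair keeps
  corner regions reachable — which is exactly the exploration deficit
  the modification exists to fix.

Determinism: one `numpy.random.Generator` per run, seeded explicitly;
the draw order is fixed (per agent: strategy coin, then the strategy's
coefficient vectors in numeric order; replacement draws after all moves
of the iteration). Identical seeds give bit-identical runs, and with QRL
off and `trial_limit=None` the MSCHO code path is bit-identical to SCHO.
The global best is the first agent attaining the minimal fitness; the
best-so-far history is nonincreasing by construction. A non-finite
objective value aborts the run naming the offending position.

## Synthetic gait cohorts

`gaitopt.synthetic` generates labeled cohorts so the full pipeline is
testable without any download. Each subject walks with a per-subject
stride frequency drawn from N(0.95, 0.05) Hz per foot (stride time
≈ 1.05 s, i.e. cadence ≈ 114 steps/min over both feet — ordinary adult
walking). Every stride lays down half-sine stance pulses on the 8
sensors of the stance foot, heel first and toe last (onset delays up to
40% of stance, stance = 65% of the stride), with a fixed
anteroposterior amplitude profile. Subject-level variation: a
multiplicative weight factor N(1, 0.12) and a left/right load share
N(0.5, 0.03). Stride times jitter i.i.d. with a baseline coefficient of
variation of 3% (healthy stride-time CV is a few percent).

A PD label applies three effects, with defaults at the strong end of
what the pipeline is expected to separate:

* amplitude reduced by 40% (`pd_amplitude_drop = 0.4`);
* stride-time CV inflated 3× (`pd_stride_cv_inflation = 3.0`);
* freezing episodes at 2/min, mean duration 1.5 s (clipped to
  [0.5, 4] s), modeled as ×0.05 multiplicative suppression of all
  channels so that window normalization never degenerates.

Additive Gaussian sensor noise (sd 3 force units against per-sensor
peaks of ~100) is truncated at zero; foot totals are channel sums by
construction. The default cohort is 10 control + 10 PD subjects at 60 s
per walk — deliberately scaled down so end-to-end experiments run in
minutes on one CPU; the full study-scale cohort (73 control + 93 PD) is
a parameter change.

What the generator does **not** emulate: real VGRF waveform-shape
differences (reduced heel-strike transients, shuffling double-support
patterns), center-of-pressure trajectories, fatigue or medication-state
drift, and sensor-specific calibration error. Passing tests therefore
demonstrate that the pipeline recovers amplitude/timing/freezing
signatures from force images, not that it reaches the published
real-data accuracies.

A consequence of the simple linear force model: per-window min–max
normalization removes most of the absolute-amplitude signal, so class
separability in the images is carried mainly by freezing bands and by
the accumulated stride-phase irregularity (a random walk reaching ~2
columns by the end of a PD window versus ~0.7 for controls at the
default image width).

## Gait I/O and image encoding

Walk files are the public gaitpdb dialect: whitespace-separated text
with time + 16 sensor forces + 2 per-foot totals at 100 Hz. The parser
enforces monotone time and nonnegative forces, and recomputes the total
columns — a disagreement above 1% of the foot's peak warns and the
recomputed sums are used.

Heel strikes are upward crossings of 5% of the foot's peak total force,
after a 50 ms moving-average smoothing (without it, sensor noise near
the threshold fires spurious events), de-bounced by a 0.3 s refractory
window. Windows span exactly 20 reference-foot (left, configurable)
strides, non-overlapping, trailing partial window dropped.

Images are 18 channel rows (16 sensors + 2 totals) plus 2 zero-padding
rows = 20 rows; the time axis is linearly resampled to 100 columns;
intensities are min–max normalized to [0, 255]. Two normalization
scopes exist: the default scales the whole slice jointly (preserving
cross-channel structure such as the left/right balance ratio and the
anteroposterior sensor profile), the alternative scales each channel row
independently (each row's maximum becomes 255). A fully zero window is
rejected; constant channels map to mid-gray.

The default train/test split unit is the window (stratified by label,
reproducible under seed), which mirrors evaluation supports counted in
windows; the subject-level unit guarantees no subject appears in both
partitions and is the leakage-safe choice for any scientific claim. Both
are exposed.

## The two-layer framework

**Layer 1.** The convolutional feature extractor is a compact numpy
network: 1–3 conv blocks (3×3 kernels, stride 1, same padding, ReLU,
2×2 max-pool), a dense bottleneck of 8–16 ReLU units (the extracted
feature vector), and a 2-way softmax head; cross-entropy loss with Adam,
batch size 16. Pooling is fixed, not searched. The searched space is
learning rate [1e-4, 1e-2], epochs [5, 25], conv layers [1, 3], units
per conv [8, 64], output features [8, 16]; integer dimensions are
decoded by rounding at evaluation time only. The layer-1 objective is
validation error on an inner 70/30 split of the training partition, and
the search stops once validation accuracy exceeds the 90% threshold.
The returned extractor is chosen by inner-validation error among the
best network encountered during the search and up to three
deterministically-seeded refits of the best configuration on the full
training partition (a ReLU network this small can die under an unlucky
initialization; selection by validation keeps a good searched network
from being discarded by a degenerate refit). The hand-written backward
pass is verified against finite differences in the test suite.

**Layer 2.** XGBoost over the extracted features with the searched
space: learning rate [0.1, 0.9], min child weight [1, 10], subsample
[0.1, 1], colsample-by-tree [0.01, 1], max depth [3, 10] (integer),
gamma [0, 0.8]; min child weight and gamma are continuous, matching
fractional published selections. Tree count is fixed at the library
default (100) and recorded in the run manifest. The optimization
objective is the pooled 5-fold stratified cross-validation error over
the training features (total misclassified over n); pooling avoids the
large tied plateaus that single small validation sets produce. Cohen's
kappa is recorded as the indicator. A failed training scores the
worst-case objective 1.0.

At the scaled-down cohort size an important degeneracy appears: with
~30 training windows the min-child-weight constraint (a hessian sum,
≈ 0.25 per sample at the first boosting round) makes roughly half its
range unable to split at all, so a large fraction of the search volume
collapses to a constant predictor with ~50% error. The search landscape
is therefore a plateau with a small good region — this, not the
classifier itself, is what stresses the optimizer's exploration
mechanisms in the end-to-end tests.

**Experiment runner.** The protocol: stratified 70/30 train/test split;
layer-1 tuning with MSCHO; feature extraction; `n_runs` independent
layer-2 optimizations (per-run seeds derived from the experiment seed);
per-run final models retrained on the full training features and scored
on the held-out test partition (error rate and kappa); summaries
best/worst/mean/median/std/var for objective and indicator; the best
run's full metric report; an untuned XGBoost baseline on the same
features. Defaults follow the study protocol: 10 agents, 15 iterations,
30 runs, 70/30 split, 90% threshold; the scaled-down configuration used
in tests and the acceptance script is 5 agents, 5 iterations, 3 runs.
Everything is reproducible from (cohort seed, experiment seed).

## Metrics

`gaitopt.metrics` computes everything from explicit 2×2 counts with PD
as the positive class: accuracy, per-class precision / sensitivity / F1
(each class treated as positive in turn), error rate = 1 − accuracy,
macro (unweighted) and support-weighted averages, and Cohen's kappa from
the row/column marginals. Zero-denominator metrics are reported as NaN
and propagate into averages rather than being coerced to 0.
`confusion_from_class_stats` reconstructs the matrix from per-class
supports and sensitivities (nearest-integer correct counts; an
inconsistency beyond one count is an error), which is how the published
benchmark tables are re-derived to six decimal places in
`gaitopt validate-tables`.

## Statistical outcome validation

Per (algorithm, problem) samples of per-run best objective values are
screened with Shapiro–Wilk at α = 0.05; constant samples are reported
as undefined rather than tested. When normality fails, the control
method is compared to each competitor with the one-sided Wilcoxon
signed-rank test (alternative: control's objective is lower) at α = 0.1,
zero differences dropped before ranking and ties mid-ranked. Identical
samples short-circuit to p = 1. Both stages are thin, documented wrappers
over scipy.stats and are calibrated in the acceptance tests (type-I rate
against its binomial tolerance; power ≥ 0.9 at a 1-sd shift, n = 30).

## Numerical and design notes

* Bound handling is clip-to-box after every move; simplest, and keeps
  the containment invariant testable.
* Integer search dimensions stay continuous inside the optimizer and are
  rounded only at decode time, so the dynamics are unaffected.
* Trials increment on strict non-improvement of the agent's own fitness
  and reset on improvement or replacement.
* Image resampling is linear interpolation; per-record normalization
  scope is the default (see above).
* The circular time-shift augmentation knob in the CNN is off by
  default: on these images the wrap seam imitates the freeze/phase-break
  cue and hurt generalization when tried.
* Known limitations: per-window evaluation with the window split unit
  shares subjects between train and test (use the subject unit for
  leakage-safe claims); the numpy CNN is single-threaded and sized for
  20×100 inputs; only binary classification is supported; competing
  metaheuristics are represented by a uniform random-search baseline.
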