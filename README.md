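# gaitopt

Metaheuristic-tuned classification of parkinsonian gait from in-sole
vertical ground reaction force (VGRF) recordings.

Parkinson's disease alters walking early: step amplitude shrinks,
stride-to-stride timing becomes irregular, and walking is interrupted by
freezing episodes. These signatures are visible in the forces that
instrumented shoe soles record (16 sensors per subject at 100 Hz, plus
per-foot totals). `gaitopt` implements a two-layer pipeline that turns
such recordings into a PD/control classifier, with both layers tuned by
a population metaheuristic:

1. walks are segmented into 20-stride windows and encoded as small
   grayscale images (channels × time, 20 × 100);
2. **layer 1** tunes a compact convolutional network (learning rate,
   epochs, conv depth/width, feature-bottleneck width) until a 90%
   accuracy threshold is passed, then uses its penultimate layer as a
   feature extractor;
3. **layer 2** tunes a gradient-boosted tree classifier (XGBoost) on the
   extracted features, minimizing classification error rate and
   recording Cohen's kappa as the indicator, over repeated independent
   runs with summary statistics and nonparametric outcome validation
   (Shapiro–Wilk screening, one-sided Wilcoxon signed-rank comparison).

## The optimizer

The tuner is the sinh–cosh optimizer (SCHO) and its modified variant
MSCHO. SCHO is a population method whose move weights are built from
hyperbolic functions of uniform draws, e.g. the exploration weight

    W1 = r3 · b1 · (cosh r4 + μ · sinh r4 − 1),   r3, r4 ~ U(0,1),

with a phase boundary `S = floor(T / ct)` (ct = 3.6) separating
exploration from exploitation, each phase with two update strategies
around the incumbent best. MSCHO adds two exploration mechanisms:

* **quasi-reflection-based learning (QRL)** — initial positions are drawn
  uniformly between a uniform base draw and the search-box midpoint,
  `x_qr ~ U((lb+ub)/2, x)`;
* **trial abandonment** — an agent whose fitness has not improved for two
  iterations is discarded and re-seeded by a fresh uniform draw paired
  with its quasi-reflection (the better of the two survives).

Classification quality is reported through the 2×2 confusion matrix:
accuracy, per-class precision/sensitivity/F1, error rate, and Cohen's
kappa `κ = (p_o − p_e) / (1 − p_e)`.

## Worked example

Generate a synthetic cohort (10 control + 10 PD subjects, 60 s walks,
with reduced PD amplitude, 3× stride-time variability and freezing
episodes), then run a scaled-down experiment (5 agents, 5 iterations,
3 runs):

```
$ gaitopt simulate --out cohort --seed 0
wrote 20 records to cohort

$ gaitopt optimize --data cohort --out run --seed 0 --agents 5 --iterations 5 --runs 3
47 images; best test error 0.071429, best kappa 0.857143, baseline error 0.214286
```

The three numbers are: the best held-out error rate across the three
tuned runs, the corresponding Cohen's kappa on the held-out windows
(1 = perfect, 0 = chance), and the error of an untuned XGBoost on the
same features — the tuned models beat the untuned baseline. `run/`
contains per-run records, convergence traces, the best model's detailed
metric report and hyperparameters, and a JSON manifest of every resolved
setting and seed.

The published benchmark tables of the three gaitpdb study splits can be
re-derived from their printed class supports and sensitivities:

```
$ gaitopt validate-tables
...
45/45 metric targets pass; 0 hyperparameter range violations
```

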