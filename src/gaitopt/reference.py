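"""Published benchmark values for the three PhysioNet gaitpdb study splits.

The public "Gait in Parkinson's Disease" database (gaitpdb/1.0.0) bundles
walks from three clinical studies — Yogev et al. (dual tasking),
Hausdorff et al. (rhythmic auditory stimulation) and Frenkel-Toledo et
al. (treadmill) — here keyed ``yogev``, ``hausdorff``, ``frenkel_toledo``.

For each split this module records, for the best tuned model
(CNN + gradient-boosted trees tuned by MSCHO):

* test-set class supports and per-class sensitivities — the inputs from
  which the 2x2 confusion matrix is reconstructed;
* the published metric values (precision/sensitivity/F1 per class, macro
  and weighted averages, accuracy, Cohen's kappa, error rate) that the
  reconstruction must reproduce;
* the realized hyperparameter selections of every compared optimizer,
  used as range-regression fixtures for the layer-2 decoder bounds.

These are frozen benchmark numbers, not computed results; everything in
:mod:`gaitopt.validate` recomputes the metric values from the supports
and sensitivities alone and compares against them.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SplitBenchmark:
    name: str
    support: tuple[int, int]  # (control, pd)
    sensitivity: tuple[float, float]  # best-model per-class sensitivity
    precision: tuple[float, float]
    f1: tuple[float, float]
    accuracy: float
    macro_precision: float
    weighted_precision: float
    macro_sensitivity: float
    weighted_sensitivity: float
    macro_f1: float
    weighted_f1: float
    kappa: float
    error_rate: float
    baseline_error_rate: float  # untuned gradient-boosting reference


BENCHMARKS: dict[str, SplitBenchmark] = {
    "yogev": SplitBenchmark(
        name="yogev",
        support=(114, 225),
        sensitivity=(0.973684, 0.968889),
        precision=(0.940678, 0.986425),
        f1=(0.956897, 0.977578),
        accuracy=0.970501,
        macro_precision=0.963552,
        weighted_precision=0.971041,
        macro_sensitivity=0.971287,
        weighted_sensitivity=0.970501,
        macro_f1=0.967238,
        weighted_f1=0.970623,
        kappa=0.934485,
        error_rate=0.029499,
        baseline_error_rate=0.056047,
    ),
    "hausdorff": SplitBenchmark(
        name="hausdorff",
        support=(75, 312),
        sensitivity=(0.960000, 0.987179),
        precision=(0.947368, 0.990354),
        f1=(0.953642, 0.988764),
        accuracy=0.981912,
        macro_precision=0.968861,
        weighted_precision=0.982023,
        macro_sensitivity=0.973590,
        weighted_sensitivity=0.981912,
        macro_f1=0.971203,
        weighted_f1=0.981958,
        kappa=0.942407,
        error_rate=0.018088,
        baseline_error_rate=0.025840,
    ),
    "frenkel_toledo": SplitBenchmark(
        name="frenkel_toledo",
        support=(87, 105),
        sensitivity=(0.954023, 0.952381),
        precision=(0.943182, 0.961538),
        f1=(0.948571, 0.956938),
        accuracy=0.953125,
        macro_precision=0.952360,
        weighted_precision=0.953221,
        macro_sensitivity=0.953202,
        weighted_sensitivity=0.953125,
        macro_f1=0.952755,
        weighted_f1=0.953147,
        kappa=0.905512,
        error_rate=0.046875,
        baseline_error_rate=0.067708,
    ),
}

# Realized layer-2 hyperparameter selections of the best model per
# optimizer: (learning_rate, min_child_weight, subsample,
# colsample_by_tree, max_depth, gamma).
HYPERPARAM_SELECTIONS: dict[str, dict[str, tuple[float, ...]]] = {
    "yogev": {
        "MSCHO": (0.900000, 7.689301, 1.000000, 0.793686, 6.000000, 0.628655),
        "SCHO": (0.726800, 4.427460, 0.404638, 0.667566, 6.225021, 0.542562),
        "SCA": (0.900000, 7.409894, 1.000000, 1.000000, 8.000000, 0.800000),
        "GA": (0.900000, 10.000000, 1.000000, 1.000000, 5.000000, 0.000000),
        "PSO": (0.900000, 10.000000, 1.000000, 1.000000, 6.000000, 0.000000),
        "FA": (0.900000, 7.435905, 1.000000, 1.000000, 9.000000, 0.800000),
        "WOA": (0.900000, 7.488228, 1.000000, 1.000000, 9.000000, 0.800000),
        "BSO": (0.563712, 9.720787, 0.809317, 1.000000, 4.000000, 0.235176),
        "RSA": (0.598110, 10.000000, 1.000000, 1.000000, 10.000000, 0.205231),
        "COA": (0.641151, 10.000000, 1.000000, 1.000000, 6.000000, 0.118814),
        "COLSHADE": (0.416614, 1.000000, 0.795437, 1.000000, 9.000000, 0.522865),
    },
    "hausdorff": {
        "MSCHO": (0.900000, 3.259372, 0.891252, 1.000000, 7.555943, 0.800000),
        "SCHO": (0.191214, 1.666386, 0.348368, 0.914698, 4.000000, 0.353234),
        "SCA": (0.100000, 1.000000, 0.954390, 1.000000, 10.000000, 0.000000),
        "GA": (0.318375, 1.000000, 1.000000, 1.000000, 7.000000, 0.800000),
        "PSO": (0.100000, 1.000000, 0.989769, 1.000000, 5.000000, 0.138171),
        "FA": (0.100000, 1.000000, 1.000000, 1.000000, 5.000000, 0.000000),
        "WOA": (0.900000, 1.000000, 1.000000, 1.000000, 10.000000, 0.243771),
        "BSO": (0.323362, 1.000000, 0.965132, 1.000000, 7.000000, 0.708029),
        "RSA": (0.900000, 1.073230, 0.193228, 0.901294, 6.000000, 0.613811),
        "COA": (0.100000, 3.423273, 0.993274, 1.000000, 10.000000, 0.405371),
        "COLSHADE": (0.100000, 2.174713, 1.000000, 0.901547, 7.000000, 0.198174),
    },
    "frenkel_toledo": {
        "MSCHO": (0.553152, 9.981037, 1.000000, 0.010000, 3.000000, 0.397994),
        "SCHO": (0.900000, 4.303456, 0.694402, 1.000000, 3.000000, 0.454477),
        "SCA": (0.648538, 1.000000, 1.000000, 1.000000, 3.000000, 0.800000),
        "GA": (0.541834, 10.000000, 1.000000, 0.010000, 3.000000, 0.037293),
        "PSO": (0.566946, 9.337266, 1.000000, 0.013087, 3.000000, 0.535184),
        "FA": (0.900000, 3.747522, 1.000000, 1.000000, 9.000000, 0.800000),
        "WOA": (0.712243, 10.000000, 1.000000, 0.010000, 10.000000, 0.800000),
        "BSO": (0.530657, 6.792584, 1.000000, 0.045359, 3.000000, 0.492458),
        "RSA": (0.737744, 10.000000, 1.000000, 0.015460, 10.000000, 0.691594),
        "COA": (0.574955, 10.000000, 1.000000, 0.040267, 3.000000, 0.758948),
        "COLSHADE": (0.571372, 10.000000, 1.000000, 0.010000, 3.000000, 0.709069),
    },
}
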