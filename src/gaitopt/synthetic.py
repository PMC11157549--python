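"""Synthetic VGRF gait cohorts with controllable parkinsonian effects.

Each subject is a periodic alternating-feet walker: every stride lays down
a half-sine stance pulse on each of 8 in-sole sensors per foot, with fixed
anteroposterior activation delays (heel fires before toe) and a per-sensor
amplitude profile.  Subject-level variation mimics the rationale for the
per-foot total columns of the real recordings: a multiplicative weight
factor and a left/right balance offset.  A PD label applies three effects:

* reduced push-off amplitude (``pd_amplitude_drop``) — hypokinetic gait;
* inflated stride-time coefficient of variation
  (``pd_stride_cv_inflation``) — timing irregularity;
* freezing episodes at ``freeze_rate`` per minute, modeled as
  multiplicative suppression (x0.05) of all channels for the episode so
  normalization never degenerates, giving the characteristic flat
  low-force runs.

Additive Gaussian sensor noise is truncated at zero; foot totals equal
the channel sums by construction.  The default cohort is a scaled-down
10+10 subjects at 60 s; the full study-scale cohort (73 control + 93 PD)
is one parameter change away.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gait_io import GaitRecord, SAMPLE_RATE

__all__ = ["GaitSimParams", "generate_subject", "generate_cohort"]

# anteroposterior sensor geometry: relative onset delay and relative
# amplitude for the 8 sensors of one foot, heel (index 0) to toe (index 7)
SENSOR_DELAYS = np.linspace(0.0, 0.4, 8)  # fraction of stance duration
SENSOR_AMPLITUDES = np.array([1.0, 0.92, 0.85, 0.78, 0.74, 0.80, 0.88, 0.96])
STANCE_FRACTION = 0.65  # stance duration as a fraction of the stride
PULSE_FRACTION = 0.6  # individual sensor pulse length within the stance
FREEZE_SUPPRESSION = 0.05


@dataclass(frozen=True)
class GaitSimParams:
    """Cohort-level simulation parameters (defaults = study conditions)."""

    n_control: int = 10
    n_pd: int = 10
    duration_s: float = 60.0
    cadence_mean_hz: float = 0.95  # per-foot stride frequency
    cadence_sd_hz: float = 0.05
    stride_cv: float = 0.03  # baseline stride-time coefficient of variation
    weight_scale: float = 0.12  # sd of the per-subject weight factor
    balance_sd: float = 0.03  # sd of the left/right load share around 0.5
    base_amplitude: float = 100.0  # peak per-sensor force, arbitrary newton-like units
    pd_amplitude_drop: float = 0.4
    pd_stride_cv_inflation: float = 3.0
    freeze_rate: float = 2.0  # episodes per minute (PD only)
    freeze_duration_s: float = 1.5  # mean episode length
    noise_sd: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pd_amplitude_drop < 1.0):
            raise ValueError("pd_amplitude_drop must lie in [0, 1)")
        for name in ("stride_cv", "weight_scale", "balance_sd", "freeze_rate", "noise_sd", "pd_stride_cv_inflation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _foot_channels(
    rng: np.random.Generator,
    n: int,
    stride_period: float,
    stride_sd: float,
    start: float,
    amplitude: float,
) -> np.ndarray:
    """(n, 8) force matrix for one foot from cumulative noisy stride times."""
    duration = n / SAMPLE_RATE
    strikes = [start]
    while strikes[-1] < duration + stride_period:
        strikes.append(strikes[-1] + max(0.2 * stride_period, rng.normal(stride_period, stride_sd)))
    stance = STANCE_FRACTION * stride_period
    pulse = PULSE_FRACTION * stance
    t = np.arange(n) / SAMPLE_RATE
    forces = np.zeros((n, 8))
    for t0 in strikes:
        for k in range(8):
            onset = t0 + SENSOR_DELAYS[k] * stance
            i0 = max(0, int(np.ceil(onset * SAMPLE_RATE)))
            i1 = min(n, int(np.floor((onset + pulse) * SAMPLE_RATE)) + 1)
            if i0 >= i1:
                continue
            phase = (t[i0:i1] - onset) / pulse
            forces[i0:i1, k] += amplitude * SENSOR_AMPLITUDES[k] * np.sin(np.pi * phase)
    return forces


def generate_subject(label: str, params: GaitSimParams, rng: np.random.Generator) -> GaitRecord:
    """One labeled synthetic walk of ``params.duration_s`` seconds."""
    if label not in ("pd", "control"):
        raise ValueError(f"label must be 'pd' or 'control', got {label!r}")
    if params.duration_s < 10.0:
        raise ValueError("duration_s must be >= 10 s")
    n = int(round(params.duration_s * SAMPLE_RATE))

    cadence = max(0.3, rng.normal(params.cadence_mean_hz, params.cadence_sd_hz))
    stride_period = 1.0 / cadence
    weight = max(0.5, rng.normal(1.0, params.weight_scale))
    left_share = float(np.clip(rng.normal(0.5, params.balance_sd), 0.3, 0.7))

    amplitude = params.base_amplitude * weight
    cv = params.stride_cv
    if label == "pd":
        amplitude *= 1.0 - params.pd_amplitude_drop
        cv *= params.pd_stride_cv_inflation
    stride_sd = cv * stride_period

    left_start = rng.uniform(0.0, 0.2)
    left = _foot_channels(rng, n, stride_period, stride_sd, left_start, amplitude * 2.0 * left_share)
    right = _foot_channels(
        rng, n, stride_period, stride_sd, left_start + stride_period / 2.0, amplitude * 2.0 * (1.0 - left_share)
    )
    forces = np.hstack([left, right])

    if label == "pd" and params.freeze_rate > 0:
        n_episodes = rng.poisson(params.freeze_rate * params.duration_s / 60.0)
        for _ in range(n_episodes):
            dur = float(np.clip(rng.exponential(params.freeze_duration_s), 0.5, 4.0))
            t0 = rng.uniform(0.0, max(params.duration_s - dur, 0.0))
            i0, i1 = int(t0 * SAMPLE_RATE), int((t0 + dur) * SAMPLE_RATE)
            forces[i0:i1] *= FREEZE_SUPPRESSION

    if params.noise_sd > 0:
        forces = np.maximum(forces + rng.normal(0.0, params.noise_sd, size=forces.shape), 0.0)

    totals = np.column_stack([forces[:, :8].sum(axis=1), forces[:, 8:].sum(axis=1)])
    return GaitRecord(
        time=np.arange(n) / SAMPLE_RATE,
        forces=forces,
        foot_totals=totals,
        subject_id="unnamed",
        label=label,
        source="synthetic",
    )


def generate_cohort(params: GaitSimParams) -> tuple[list[GaitRecord], pd.DataFrame]:
    """``n_control + n_pd`` labeled subjects, reproducible under the seed."""
    rng = np.random.default_rng(params.seed)
    records: list[GaitRecord] = []
    rows = []
    for label, count in (("control", params.n_control), ("pd", params.n_pd)):
        for i in range(count):
            rec = generate_subject(label, params, rng)
            rec.subject_id = f"{label}{i:03d}"
            records.append(rec)
            rows.append({"subject": rec.subject_id, "label": label, "duration_s": rec.duration})
    return records, pd.DataFrame(rows)
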