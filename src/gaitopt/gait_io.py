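"""VGRF walk-record I/O, step detection, windowing and image encoding.

The on-disk dialect is the public gaitpdb layout: whitespace/tab-separated
text, 19 numeric columns per row — time in seconds, 16 in-sole vertical
ground reaction force sensors sampled at 100 Hz (8 per foot, left then
right), and two per-foot total-force columns.  Downstream, walks are cut
into windows of a fixed number of strides and each window is encoded as a
small fixed-size grayscale image (channels x time) for the convolutional
feature extractor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GaitRecord",
    "StepSegmentation",
    "GaitImage",
    "ParseError",
    "TooShortRecordError",
    "load_gaitpdb_record",
    "write_gaitpdb_record",
    "detect_steps",
    "window_by_steps",
    "segment_to_image",
    "split_train_test",
]

N_SENSORS = 16
N_COLUMNS = 19  # time + 16 sensors + 2 foot totals
SAMPLE_RATE = 100.0
LEFT = slice(0, 8)
RIGHT = slice(8, 16)


class ParseError(ValueError):
    pass


class TooShortRecordError(ValueError):
    pass


@dataclass
class GaitRecord:
    """Time-stamped 18-channel force series with subject label."""

    time: np.ndarray  # (n,) seconds, uniform 0.01 s steps
    forces: np.ndarray  # (n, 16) VGRF per sensor
    foot_totals: np.ndarray  # (n, 2) left, right sums
    subject_id: str
    label: str  # "pd" | "control"
    source: str = "synthetic"

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / SAMPLE_RATE

    @property
    def n_samples(self) -> int:
        return self.time.size

    def slice(self, start: int, stop: int) -> "GaitRecord":
        return replace(
            self,
            time=self.time[start:stop],
            forces=self.forces[start:stop],
            foot_totals=self.foot_totals[start:stop],
        )


@dataclass(frozen=True)
class StepSegmentation:
    """Heel-strike sample indices and stride times per foot."""

    heel_strikes: dict[str, np.ndarray]  # foot -> strictly increasing indices
    stride_times: dict[str, np.ndarray]  # foot -> seconds, > 0


@dataclass
class GaitImage:
    """Fixed-shape grayscale window (rows = channels, columns = time)."""

    pixels: np.ndarray  # (20, width), intensities in [0, 255]
    label: str
    subject_id: str
    window_index: int = 0


def load_gaitpdb_record(
    path, subject_id: str | None = None, label: str = "unknown"
) -> GaitRecord:
    """Parse one walk file; recompute foot totals and cross-check the file's.

    A total-column disagreement above 1% of the foot's peak total raises a
    warning and the recomputed sums are used.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != N_COLUMNS:
                raise ParseError(f"{path}:{lineno}: expected {N_COLUMNS} columns, found {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
    if not rows:
        raise ParseError(f"{path}: empty file")
    data = np.asarray(rows, dtype=float)
    time = data[:, 0]
    forces = data[:, 1 : 1 + N_SENSORS]
    file_totals = data[:, 1 + N_SENSORS :]
    if np.any(np.diff(time) <= 0):
        bad = int(np.argmax(np.diff(time) <= 0)) + 2
        raise ParseError(f"{path}:{bad}: non-monotone time column")
    if np.any(forces < 0):
        bad = int(np.argmax(np.any(forces < 0, axis=1))) + 1
        raise ParseError(f"{path}:{bad}: negative force value")
    totals = np.column_stack([forces[:, LEFT].sum(axis=1), forces[:, RIGHT].sum(axis=1)])
    scale = np.maximum(totals.max(axis=0), 1e-12)
    if np.any(np.abs(file_totals - totals).max(axis=0) > 0.01 * scale):
        warnings.warn(f"{path}: foot-total columns disagree with channel sums by >1%; recomputed sums used")
    else:
        totals = file_totals
    return GaitRecord(
        time=time,
        forces=forces,
        foot_totals=totals,
        subject_id=subject_id or path.stem,
        label=label,
        source=str(path),
    )


def write_gaitpdb_record(record: GaitRecord, path) -> None:
    """Write the 19-column dialect with full float precision (round-trip exact)."""
    data = np.column_stack([record.time, record.forces, record.foot_totals])
    np.savetxt(path, data, fmt="%.17g", delimiter="\t")


def detect_steps(record: GaitRecord, threshold_fraction: float = 0.05) -> StepSegmentation:
    """Heel strikes as upward threshold crossings of each foot's total force.

    The total is first smoothed with a 50 ms moving average so sensor
    noise near the threshold cannot fire spurious events; the threshold is
    ``threshold_fraction`` of the smoothed foot's peak total and a 0.3 s
    refractory window suppresses residual chatter around contact.
    """
    if record.duration < 2.0:
        raise TooShortRecordError("need at least 2 s of signal for step detection")
    refractory = int(round(0.3 * SAMPLE_RATE))
    kernel = np.ones(max(1, int(round(0.05 * SAMPLE_RATE))))
    kernel /= kernel.size
    strikes: dict[str, np.ndarray] = {}
    stride_times: dict[str, np.ndarray] = {}
    for i, foot in enumerate(("left", "right")):
        total = np.convolve(record.foot_totals[:, i], kernel, mode="same")
        thr = threshold_fraction * total.max()
        if thr <= 0:
            raise TooShortRecordError(f"{foot} foot carries no force")
        above = total >= thr
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
        kept: list[int] = []
        for c in crossings:
            if not kept or c - kept[-1] >= refractory:
                kept.append(int(c))
        if len(kept) < 2:
            raise TooShortRecordError(f"fewer than 2 heel strikes detected on {foot} foot")
        idx = np.asarray(kept, dtype=int)
        strikes[foot] = idx
        stride_times[foot] = np.diff(record.time[idx])
    return StepSegmentation(heel_strikes=strikes, stride_times=stride_times)


def window_by_steps(
    record: GaitRecord,
    seg: StepSegmentation,
    steps_per_window: int = 20,
    reference_foot: str = "left",
) -> list[GaitRecord]:
    """Non-overlapping slices spanning ``steps_per_window`` reference-foot strides."""
    idx = seg.heel_strikes[reference_foot]
    n_strides = idx.size - 1
    n_windows = n_strides // steps_per_window
    if n_windows == 0:
        warnings.warn(f"only {n_strides} strides available; need {steps_per_window} for one window")
        return []
    return [
        record.slice(int(idx[k * steps_per_window]), int(idx[(k + 1) * steps_per_window]))
        for k in range(n_windows)
    ]


def segment_to_image(
    window: GaitRecord,
    width: int = 100,
    pad_to_20: bool = True,
    binarize: bool = False,
    normalization: str = "record",
) -> GaitImage:
    """Encode a window as a (20 x width) grayscale matrix.

    Rows are the 18 data channels (16 sensors then 2 foot totals) plus two
    zero rows of padding (``pad_to_20``); the time axis is linearly
    resampled to ``width`` columns; intensities are min-max normalized to
    [0, 255] over the whole slice (``normalization="record"``, the
    default, which preserves cross-channel amplitude structure such as
    left/right balance) or per channel row (``"channel"``).  Constant
    input maps to mid-gray 127.5 — except a fully zero window, which is
    rejected as unnormalizable.
    """
    if window.n_samples == 0:
        raise ValueError("empty window")
    channels = np.column_stack([window.forces, window.foot_totals]).T  # (18, n)
    if not np.any(channels):
        raise ValueError("all-zero window cannot be normalized")
    if normalization not in ("record", "channel"):
        raise ValueError(f"unknown normalization scope {normalization!r}")
    t_new = np.linspace(window.time[0], window.time[-1], width)
    resampled = np.vstack([np.interp(t_new, window.time, ch) for ch in channels])
    if normalization == "record":
        lo = np.full((resampled.shape[0], 1), resampled.min())
        hi = np.full((resampled.shape[0], 1), resampled.max())
    else:
        lo = resampled.min(axis=1, keepdims=True)
        hi = resampled.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span.ravel() == 0
    span[flat.reshape(-1, 1)] = 1.0
    pixels = (resampled - lo) / span * 255.0
    pixels[flat] = 127.5
    if binarize:
        pixels = np.where(pixels >= 127.5, 255.0, 0.0)
    if pad_to_20:
        pixels = np.vstack([pixels, np.zeros((2, width))])
    return GaitImage(pixels=pixels, label=window.label, subject_id=window.subject_id)


def split_train_test(
    images: list[GaitImage],
    test_fraction: float = 0.3,
    unit: str = "window",
    rng: np.random.Generator | int | None = None,
) -> tuple[list[GaitImage], list[GaitImage]]:
    """Stratified train/test split, by window or by whole subject.

    The window unit reproduces per-window evaluation supports; the subject
    unit guarantees no subject contributes to both sets (leakage-safe).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = {img.label for img in images}
    if len(labels) < 2:
        raise ValueError("both classes must be present for a stratified split")
    if unit not in ("window", "subject"):
        raise ValueError(f"unknown split unit {unit!r}")
    train: list[GaitImage] = []
    test: list[GaitImage] = []
    for label in sorted(labels):
        group = [img for img in images if img.label == label]
        if unit == "window":
            order = rng.permutation(len(group))
            n_test = int(round(test_fraction * len(group)))
            test_idx = set(order[:n_test].tolist())
            for i, img in enumerate(group):
                (test if i in test_idx else train).append(img)
        else:
            subjects = sorted({img.subject_id for img in group})
            order = rng.permutation(len(subjects))
            n_test = max(1, int(round(test_fraction * len(subjects))))
            test_subjects = {subjects[i] for i in order[:n_test]}
            for img in group:
                (test if img.subject_id in test_subjects else train).append(img)
    return train, test


def save_images(images: list[GaitImage], out_dir, manifest_name: str = "manifest.tsv") -> Path:
    """Write PNG files plus a tab-separated manifest (path, subject, label, window)."""
    from PIL import Image  # optional output path only

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["path\tsubject\tlabel\twindow"]
    for i, img in enumerate(images):
        name = f"{img.subject_id}_w{img.window_index:03d}.png"
        Image.fromarray(np.round(img.pixels).astype(np.uint8), mode="L").save(out_dir / name)
        lines.append(f"{name}\t{img.subject_id}\t{img.label}\t{img.window_index}")
    manifest = out_dir / manifest_name
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
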