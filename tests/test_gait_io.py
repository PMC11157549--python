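"""Walk-record parsing, step detection, windowing, image encoding, splitting."""

import numpy as np
import pytest

from gaitopt.gait_io import (
    GaitRecord,
    ParseError,
    TooShortRecordError,
    detect_steps,
    load_gaitpdb_record,
    SAMPLE_RATE,
    segment_to_image,
    split_train_test,
    window_by_steps,
    write_gaitpdb_record,
)
from gaitopt.synthetic import GaitSimParams, generate_subject


def square_wave_record(freq_hz=1.0, duration=10.0, rate=SAMPLE_RATE):
    """Both feet stepping as clean square waves at the given stride rate."""
    n = int(duration * rate)
    t = np.arange(n) / rate
    on = ((t * freq_hz) % 1.0) < 0.4
    forces = np.zeros((n, 16))
    forces[:, :8] = np.where(on[:, None], 50.0, 0.0)
    forces[:, 8:] = np.where(~on[:, None], 50.0, 0.0)
    totals = np.column_stack([forces[:, :8].sum(1), forces[:, 8:].sum(1)])
    return GaitRecord(time=t, forces=forces, foot_totals=totals, subject_id="sq", label="control")


@pytest.fixture
def synthetic_record():
    rng = np.random.default_rng(3)
    return generate_subject("control", GaitSimParams(seed=3, duration_s=30.0), rng)


class TestParsing:
    def test_round_trip_is_bit_exact(self, tmp_path, synthetic_record):
        path = tmp_path / "walk.txt"
        write_gaitpdb_record(synthetic_record, path)
        loaded = load_gaitpdb_record(path, label="control")
        assert np.array_equal(loaded.forces, synthetic_record.forces)
        assert np.array_equal(loaded.time, synthetic_record.time)

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("\t".join(["0.01"] * 17) + "\n")
        with pytest.raises(ParseError, match="bad.txt:1"):
            load_gaitpdb_record(path)

    def test_non_monotone_time_rejected(self, tmp_path):
        rows = ["\t".join(["0.02"] + ["1"] * 18), "\t".join(["0.01"] + ["1"] * 18)]
        path = tmp_path / "time.txt"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(ParseError, match="non-monotone"):
            load_gaitpdb_record(path)

    def test_negative_force_rejected(self, tmp_path):
        path = tmp_path / "neg.txt"
        path.write_text("\t".join(["0.01"] + ["-1"] + ["1"] * 17) + "\n")
        with pytest.raises(ParseError, match="negative"):
            load_gaitpdb_record(path)

    def test_corrupted_totals_warn_and_recompute(self, tmp_path, synthetic_record):
        path = tmp_path / "corrupt.txt"
        corrupted = GaitRecord(
            time=synthetic_record.time,
            forces=synthetic_record.forces,
            foot_totals=synthetic_record.foot_totals * 1.5,  # off by 50%
            subject_id="c",
            label="control",
        )
        write_gaitpdb_record(corrupted, path)
        with pytest.warns(UserWarning, match="recomputed"):
            loaded = load_gaitpdb_record(path)
        expected = np.column_stack(
            [synthetic_record.forces[:, :8].sum(1), synthetic_record.forces[:, 8:].sum(1)]
        )
        assert np.allclose(loaded.foot_totals, expected)


class TestStepDetection:
    def test_square_wave_strike_count_and_stride_times(self):
        seg = detect_steps(square_wave_record(freq_hz=1.0, duration=10.0))
        assert 9 <= seg.heel_strikes["left"].size <= 10
        assert np.allclose(seg.stride_times["left"], 1.0, atol=0.02)

    def test_all_zero_forces_signal_too_short(self):
        rec = square_wave_record()
        rec = GaitRecord(rec.time, np.zeros_like(rec.forces), np.zeros_like(rec.foot_totals), "z", "control")
        with pytest.raises(TooShortRecordError):
            detect_steps(rec)

    def test_short_record_rejected(self):
        with pytest.raises(TooShortRecordError):
            detect_steps(square_wave_record(duration=1.0))

    def test_stride_times_are_positive_and_indices_increasing(self, synthetic_record):
        seg = detect_steps(synthetic_record)
        for foot in ("left", "right"):
            assert np.all(np.diff(seg.heel_strikes[foot]) > 0)
            assert np.all(seg.stride_times[foot] > 0)


class TestWindowing:
    @pytest.mark.parametrize("n_strides,expected", [(45, 2), (19, 0), (40, 2), (20, 1)])
    def test_window_counts(self, n_strides, expected):
        duration = n_strides + 2.0
        rec = square_wave_record(freq_hz=1.0, duration=duration)
        seg = detect_steps(rec)
        # trim the segmentation to exactly n_strides strides
        strikes = {f: seg.heel_strikes[f][: n_strides + 1] for f in seg.heel_strikes}
        seg = type(seg)(heel_strikes=strikes, stride_times=seg.stride_times)
        if expected == 0:
            with pytest.warns(UserWarning):
                assert window_by_steps(rec, seg) == []
        else:
            windows = window_by_steps(rec, seg)
            assert len(windows) == expected

    def test_windows_are_disjoint_and_cover_consecutive_strides(self, synthetic_record):
        seg = detect_steps(synthetic_record)
        windows = window_by_steps(synthetic_record, seg, steps_per_window=10)
        ends = [w.time[-1] for w in windows]
        starts = [w.time[0] for w in windows]
        assert all(e <= s + 1e-9 for e, s in zip(ends, starts[1:]))


class TestImageEncoding:
    def test_shape_contract(self, synthetic_record):
        seg = detect_steps(synthetic_record)
        windows = window_by_steps(synthetic_record, seg, steps_per_window=10)
        img = segment_to_image(windows[0])
        assert img.pixels.shape == (20, 100)
        assert img.pixels.min() >= 0 and img.pixels.max() <= 255

    def test_constant_force_maps_to_mid_gray(self):
        n = 300
        rec = GaitRecord(
            time=np.arange(n) / SAMPLE_RATE,
            forces=np.full((n, 16), 5.0),
            foot_totals=np.full((n, 2), 40.0),
            subject_id="c",
            label="control",
        )
        img = segment_to_image(rec, normalization="channel")
        assert np.all(img.pixels[:18] == 127.5)
        # record scope: constant channels span the global range instead
        img2 = segment_to_image(rec, normalization="record")
        assert img2.pixels[:18].min() == 0.0 and img2.pixels[:18].max() == 255.0

    def test_all_zero_slice_rejected(self):
        n = 300
        rec = GaitRecord(np.arange(n) / SAMPLE_RATE, np.zeros((n, 16)), np.zeros((n, 2)), "z", "control")
        with pytest.raises(ValueError, match="zero"):
            segment_to_image(rec)

    def test_channel_scope_puts_255_at_each_channel_max(self, synthetic_record):
        seg = detect_steps(synthetic_record)
        windows = window_by_steps(synthetic_record, seg, steps_per_window=10)
        img = segment_to_image(windows[0], normalization="channel")
        assert np.allclose(img.pixels[:18].max(axis=1), 255.0)

    def test_record_scope_is_globally_normalized(self, synthetic_record):
        seg = detect_steps(synthetic_record)
        windows = window_by_steps(synthetic_record, seg, steps_per_window=10)
        img = segment_to_image(windows[0], normalization="record")
        assert img.pixels[:18].max() == pytest.approx(255.0)
        assert img.pixels[:18].min() == pytest.approx(0.0)

    def test_determinism(self, synthetic_record):
        seg = detect_steps(synthetic_record)
        w = window_by_steps(synthetic_record, seg, steps_per_window=10)[0]
        assert np.array_equal(segment_to_image(w).pixels, segment_to_image(w).pixels)


class TestSplit:
    def test_window_split_sizes(self, default_cohort_images):
        train, test = split_train_test(default_cohort_images, 0.3, rng=0)
        n = len(default_cohort_images)
        assert len(train) + len(test) == n
        assert abs(len(test) - 0.3 * n) <= 2  # per-class rounding

    def test_subject_split_has_no_leakage(self, default_cohort_images):
        train, test = split_train_test(default_cohort_images, 0.3, unit="subject", rng=0)
        assert {i.subject_id for i in train}.isdisjoint({i.subject_id for i in test})

    def test_same_seed_gives_identical_partition(self, default_cohort_images):
        a = split_train_test(default_cohort_images, 0.3, rng=42)
        b = split_train_test(default_cohort_images, 0.3, rng=42)
        assert [id(i) for i in a[0]] == [id(i) for i in b[0]]

    def test_single_class_rejected(self, default_cohort_images):
        only_pd = [i for i in default_cohort_images if i.label == "pd"]
        with pytest.raises(ValueError):
            split_train_test(only_pd, 0.3, rng=0)
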