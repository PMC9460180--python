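"""Signal reading, scaling, drive isolation, windowing and fold construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from acticam.prep import (
    DatasetSpec,
    apply_task_exclusions,
    enumerate_windows,
    extract_drive,
    make_folds,
    sample_random_window,
    scale_to_g,
)
from acticam.signals import AccelerometrySignal, read_accel_csv

from conftest import make_drive


class TestReadAccelCsv:
    def test_valid_file(self, tmp_path):
        path = tmp_path / "ok.csv"
        path.write_text(
            "time,x,y,z\n"
            "2022-03-07T08:10:00.000,0.1,0.2,0.9\n"
            "2022-03-07T08:10:00.050,0.1,0.2,0.9\n"
            "2022-03-07T08:10:00.100,0.2,0.1,0.8\n"
        )
        signal = read_accel_csv(path)
        assert len(signal) == 3
        assert signal.sample_rate == pytest.approx(20.0)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,x,y\n2022-03-07T08:10:00.000,0.1,0.2\n")
        with pytest.raises(ValueError, match="z"):
            read_accel_csv(path)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time,x,y,z\n"
            "2022-03-07T08:10:00.100,0,0,1\n"
            "2022-03-07T08:10:00.050,0,0,1\n"
        )
        with pytest.raises(ValueError, match="increasing"):
            read_accel_csv(path)

    def test_non_uniform_spacing_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time,x,y,z\n"
            "2022-03-07T08:10:00.000,0,0,1\n"
            "2022-03-07T08:10:00.050,0,0,1\n"
            "2022-03-07T08:10:00.500,0,0,1\n"
        )
        with pytest.raises(ValueError, match="uniform"):
            read_accel_csv(path)


class TestScaleToG:
    def test_linear_8bit_mapping(self):
        scaled = scale_to_g(np.array([127.5, 255.0, 0.0]), "linear", offset=127.5, gain=31.875)
        assert scaled == pytest.approx([0.0, 4.0, -4.0])

    def test_identity_passthrough(self):
        assert scale_to_g(np.array([0.98]))[0] == pytest.approx(0.98)

    def test_out_of_range_clipped_and_logged(self, caplog):
        with caplog.at_level("WARNING"):
            scaled = scale_to_g(np.array([5.0, -6.0, 1.0]))
        assert scaled == pytest.approx([4.0, -4.0, 1.0])
        assert "2 samples" in caplog.text

    def test_zero_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            scale_to_g(np.array([1.0]), "linear", offset=0.0, gain=0.0)


class TestExtractDrive:
    @staticmethod
    def _recording(n=100000, rate=20.0):
        return AccelerometrySignal(
            np.datetime64("2022-03-07T08:00:00"), rate, np.tile([0.0, 0.0, 1.0], (n, 1))
        )

    def test_slice_length(self):
        drive = extract_drive(self._recording(), "2022-03-07T08:10:00", 1200.0)
        assert len(drive) == 24000

    def test_start_before_recording_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            extract_drive(self._recording(), "2022-03-07T07:59:00", 60.0)

    def test_start_on_sample_boundary(self):
        drive = extract_drive(self._recording(), "2022-03-07T08:00:00.050", 1.0)
        assert drive.start_time == np.datetime64("2022-03-07T08:00:00.050")


class TestTaskExclusions:
    @staticmethod
    def _ten_drives():
        return [
            make_drive(day=day, session=session)
            for day in range(1, 6)
            for session in ("pre_shift", "post_shift")
        ]

    def test_sitting_task_drops_first_drive(self):
        kept = apply_task_exclusions(self._ten_drives(), "sitting_history")
        assert len(kept) == 9
        assert not any(d.day == 1 and d.session == "pre_shift" for d in kept)

    def test_sleep_task_keeps_all(self):
        assert len(apply_task_exclusions(self._ten_drives(), "sleep_history")) == 10

    def test_missing_first_drive_unchanged(self):
        drives = [d for d in self._ten_drives() if not (d.day == 1 and d.session == "pre_shift")]
        assert [id(d) for d in apply_task_exclusions(drives, "sitting_history")] == [id(d) for d in drives]


class TestEnumerateWindows:
    @pytest.mark.parametrize("n,length,stride,expected", [(24000, 4096, 4096, 5), (24000, 4096, 1024, 20), (512, 512, 64, 1)])
    def test_window_counts(self, n, length, stride, expected):
        windows = enumerate_windows(make_drive(n=n), "sitting_history", length, stride)
        assert len(windows) == expected
        assert [w.start_index for w in windows] == sorted(w.start_index for w in windows)

    def test_labels_inherited(self):
        drive = make_drive(activity="breaking_up_sitting", sleep="sleep_5h")
        assert all(w.label == 0 for w in enumerate_windows(drive, "sitting_history", 100, 50))
        assert all(w.label == 1 for w in enumerate_windows(drive, "sleep_history", 100, 50))

    def test_too_long_window_gives_empty(self):
        assert enumerate_windows(make_drive(n=50), "sitting_history", 100, 10) == []

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(8, 120), length=st.integers(1, 120), stride=st.integers(1, 60))
    def test_count_matches_exhaustive_enumeration(self, n, length, stride):
        drive = make_drive(n=n)
        windows = enumerate_windows(drive, "sitting_history", length, stride)
        brute = [s for s in range(0, n) if s % stride == 0 and s + length <= n]
        assert len(windows) == len(brute)
        assert [w.start_index for w in windows] == brute


class TestRandomWindows:
    def test_full_length_window_starts_at_zero(self):
        drive = make_drive(n=64)
        w = sample_random_window(drive, "sitting_history", 64, np.random.default_rng(0))
        assert w.start_index == 0

    def test_start_distribution_uniform(self):
        drive = make_drive(n=2400)
        rng = np.random.default_rng(7)
        length = 512
        starts = [sample_random_window(drive, "sitting_history", length, rng).start_index for _ in range(10000)]
        n_slots = 2400 - length + 1
        # chi-square over 16 coarse bins at alpha = 0.01
        bins = np.minimum(np.array(starts) * 16 // n_slots, 15)
        observed = np.bincount(bins, minlength=16)
        chi2 = ((observed - 10000 / 16) ** 2 / (10000 / 16)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=15)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            sample_random_window(make_drive(n=10), "sitting_history", 11, np.random.default_rng(0))

    def test_reproducible_given_rng_state(self):
        drive = make_drive(n=500)
        a = [sample_random_window(drive, "sitting_history", 64, np.random.default_rng(3)).start_index for _ in range(5)]
        b = [sample_random_window(drive, "sitting_history", 64, np.random.default_rng(3)).start_index for _ in range(5)]
        assert a == b


class TestMakeFolds:
    def test_window_level_80_20(self):
        units = list(range(100))
        folds = make_folds(units, 5, "window_level", seed=1)
        assert all(len(f.val_units) == 20 and len(f.train_units) == 80 for f in folds)

    def test_validation_sets_partition_the_units(self):
        units = list(range(103))
        folds = make_folds(units, 5, "window_level", seed=2)
        all_val = [u for f in folds for u in f.val_units]
        assert sorted(all_val) == units
        for f in folds:
            assert set(f.train_units).isdisjoint(f.val_units)
            assert sorted(f.train_units + list(f.val_units)) == units

    def test_participant_level_no_leakage(self):
        participants = [f"P{i}" for i in range(10)]
        labels = [i % 2 for i in range(10)]
        folds = make_folds(participants, 5, "participant_level", seed=3, labels=labels)
        for f in folds:
            assert len(f.val_units) == 2
            assert set(f.train_units).isdisjoint(f.val_units)

    def test_participant_level_stratified(self):
        participants = [f"P{i}" for i in range(8)]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        lab = dict(zip(participants, labels))
        for f in make_folds(participants, 4, "participant_level", seed=5, labels=labels):
            assert {lab[p] for p in f.val_units} == {0, 1}

    def test_same_seed_identical(self):
        units = list(range(50))
        a = make_folds(units, 5, "window_level", seed=9)
        b = make_folds(units, 5, "window_level", seed=9)
        assert [f.val_units for f in a] == [f.val_units for f in b]

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_folds([1, 2], 3)


def test_dataset_spec_validation():
    with pytest.raises(ValueError, match="task"):
        DatasetSpec(task="walking")
    with pytest.raises(ValueError, match="k"):
        DatasetSpec(k=1)
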