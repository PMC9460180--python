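"""Drive isolation, scaling, task exclusions, windowing and CV folds.

Two binary tasks are defined over the same recordings:

* ``sitting_history`` — sitting (positive) vs breaking up sitting.  The
  pre-shift drive of experimental day 1 is excluded because the activity
  manipulation had not yet begun at that point in the protocol.
* ``sleep_history`` — 5-h (positive) vs 9-h sleep opportunity.  All drives
  are kept: the first restricted/full sleep night precedes the first drive.

Cross-validation supports two granularities.  ``window_level`` shuffles the
enumerated windows and partitions them 80/20 over k folds.  Because
overlapping windows from one drive can then straddle train and validation,
``participant_level`` is also provided: whole participants are assigned to
folds (stratified by label), so no participant contributes to both sides of
a fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    CohortConfig,
    MovementModelParams,
    ParticipantProfile,
    drive_schedule,
    drive_seed,
    drive_start_time,
    generate_cohort,
    generate_drive_signal,
    participant_params,
)
from .signals import G_RANGE, AccelerometrySignal, read_accel_csv

logger = logging.getLogger(__name__)

TASKS = ("sitting_history", "sleep_history")
#: Positive-class (label 1) condition for each task.
POSITIVE_CLASS = {"sitting_history": "sitting", "sleep_history": "sleep_5h"}


@dataclass
class DriveRecord:
    participant_id: str
    day: int  # experimental day, 1..5
    session: str  # pre_shift | post_shift
    signal: AccelerometrySignal
    activity_class: str
    sleep_class: str

    def label(self, task: str) -> int:
        condition = self.activity_class if task == "sitting_history" else self.sleep_class
        return int(condition == POSITIVE_CLASS[task])

    @property
    def drive_id(self) -> str:
        return f"{self.participant_id}_E{self.day}_{self.session}"


@dataclass
class LabelledWindow:
    values: np.ndarray  # (3, L) in g
    label: int
    participant_id: str
    drive_id: str
    start_index: int


@dataclass
class DatasetSpec:
    task: str = "sitting_history"
    window_length: int = 4096
    eval_stride: int = 1024
    split_mode: str = "window_level"
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.window_length < 1 or self.eval_stride < 1:
            raise ValueError("window_length and eval_stride must be >= 1")
        if self.split_mode not in ("window_level", "participant_level"):
            raise ValueError("split_mode must be 'window_level' or 'participant_level'")
        if self.k < 2:
            raise ValueError("k must be >= 2")


# ---------------------------------------------------------------------------
# Scaling and drive isolation
# ---------------------------------------------------------------------------


def scale_to_g(raw: np.ndarray, mapping: str = "identity", offset: float = 0.0, gain: float = 1.0) -> np.ndarray:
    """Map raw sensor counts to the +-4 g scale.

    ``identity`` passes g-unit data through; ``linear`` applies
    ``(raw - offset) / gain``.  Values beyond +-4 g are clipped and the
    clipped-sample count is logged.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if mapping == "identity":
        scaled = raw.copy()
    elif mapping == "linear":
        if gain == 0:
            raise ValueError("linear scaling requires a non-zero gain")
        scaled = (raw - offset) / gain
    else:
        raise ValueError("mapping must be 'identity' or 'linear'")
    clipped = int(np.count_nonzero((scaled < -G_RANGE) | (scaled > G_RANGE)))
    if clipped:
        logger.warning("clipped %d samples outside the +-%g g range", clipped, G_RANGE)
    return np.clip(scaled, -G_RANGE, G_RANGE)


def extract_drive(signal: AccelerometrySignal, start_time, duration: float) -> AccelerometrySignal:
    """Slice out ``[start_time, start_time + duration)`` from a recording.

    The slice begins at the first sample at or after ``start_time`` and has
    ``round(duration * sample_rate)`` samples; a window that is not fully
    covered by the recording is an error.
    """
    start_idx = signal.time_to_index(np.datetime64(start_time, "ms"))
    n = int(round(duration * signal.sample_rate))
    if start_idx < 0 or start_idx + n > len(signal):
        raise ValueError(
            f"drive [{start_time}, +{duration}s) not covered by recording "
            f"({len(signal)} samples from {signal.start_time})"
        )
    return AccelerometrySignal(
        start_time=signal.timestamps()[start_idx],
        sample_rate=signal.sample_rate,
        data=signal.data[start_idx : start_idx + n],
    )


def apply_task_exclusions(drives: list[DriveRecord], task: str) -> list[DriveRecord]:
    """Drop the day-1 pre-shift drive for the sitting task; keep all for sleep."""
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    if task == "sleep_history":
        return list(drives)
    return [d for d in drives if not (d.day == 1 and d.session == "pre_shift")]


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def enumerate_windows(drive: DriveRecord, task: str, length: int, stride: int) -> list[LabelledWindow]:
    """All windows at fixed stride: floor((N - L)/stride) + 1 of them, in order."""
    n = len(drive.signal)
    if length > n:
        logger.warning("window length %d exceeds drive length %d; no windows", length, n)
        return []
    label = drive.label(task)
    starts = range(0, n - length + 1, stride)
    return [
        LabelledWindow(
            values=np.ascontiguousarray(drive.signal.data[s : s + length].T),
            label=label,
            participant_id=drive.participant_id,
            drive_id=drive.drive_id,
            start_index=s,
        )
        for s in starts
    ]


def sample_random_window(drive: DriveRecord, task: str, length: int, rng: np.random.Generator) -> LabelledWindow:
    """One window at a start offset uniform on {0, ..., N - L}."""
    n = len(drive.signal)
    if length > n:
        raise ValueError(f"window length {length} exceeds drive length {n}")
    s = int(rng.integers(0, n - length + 1))
    return LabelledWindow(
        values=np.ascontiguousarray(drive.signal.data[s : s + length].T),
        label=drive.label(task),
        participant_id=drive.participant_id,
        drive_id=drive.drive_id,
        start_index=s,
    )


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


@dataclass
class Fold:
    index: int
    train_units: list
    val_units: list


def make_folds(units: list, k: int, split_mode: str = "window_level", seed: int = 0, labels: list | None = None) -> list[Fold]:
    """k train/validation partitions with disjoint, jointly exhaustive validation sets.

    ``units`` are windows (window_level) or participant ids
    (participant_level).  With labels given, participant-level assignment is
    stratified so each fold's validation set covers both classes where
    possible.
    """
    if split_mode not in ("window_level", "participant_level"):
        raise ValueError("split_mode must be 'window_level' or 'participant_level'")
    if len(units) < k:
        raise ValueError(f"cannot make {k} folds from {len(units)} units")
    rng = np.random.default_rng(seed)
    order = np.arange(len(units))
    if split_mode == "participant_level" and labels is not None:
        # shuffle within class, interleave classes, then deal round-robin
        by_class: dict = {}
        for i, lab in enumerate(labels):
            by_class.setdefault(lab, []).append(i)
        interleaved: list[int] = []
        pools = [list(rng.permutation(idx)) for idx in by_class.values()]
        while any(pools):
            for pool in pools:
                if pool:
                    interleaved.append(int(pool.pop()))
        order = np.array(interleaved)
    else:
        rng.shuffle(order)
    # contiguous chunks: with class-interleaved order, consecutive units
    # alternate classes, so each validation fold covers both classes
    val_sets = np.array_split(order, k)
    folds = []
    for i, val in enumerate(val_sets):
        val_mask = np.zeros(len(units), dtype=bool)
        val_mask[val] = True
        folds.append(
            Fold(
                index=i,
                train_units=[units[j] for j in np.flatnonzero(~val_mask)],
                val_units=[units[j] for j in sorted(val)],
            )
        )
    return folds


# ---------------------------------------------------------------------------
# Building drive sets (in memory or from disk)
# ---------------------------------------------------------------------------


def build_drive_records(
    config: CohortConfig,
    profiles: list[ParticipantProfile] | None = None,
    base_params: MovementModelParams | None = None,
) -> list[DriveRecord]:
    """Simulate every drive of the cohort directly into DriveRecords."""
    if profiles is None:
        profiles, _ = generate_cohort(config)
    base = base_params or MovementModelParams()
    records = []
    for p in profiles:
        params = participant_params(p, config, base)
        for day, session in drive_schedule(config):
            signal = generate_drive_signal(
                p,
                params,
                seed=drive_seed(config.seed, p.participant_id, day, session),
                sample_rate=config.sample_rate,
                duration=config.drive_duration,
                start_time=drive_start_time(day, session),
            )
            records.append(
                DriveRecord(
                    participant_id=p.participant_id,
                    day=day,
                    session=session,
                    signal=signal,
                    activity_class=p.activity_class,
                    sleep_class=p.sleep_class,
                )
            )
    return records


def load_drives(data_dir, manifest) -> list[DriveRecord]:
    """Read per-drive CSVs referenced by a manifest frame into DriveRecords."""
    from pathlib import Path

    data_dir = Path(data_dir)
    records = []
    for row in manifest.itertuples(index=False):
        path = data_dir / f"{row.participant_id}_E{row.day}_{row.session}.csv"
        signal = read_accel_csv(path)
        records.append(
            DriveRecord(
                participant_id=row.participant_id,
                day=int(row.day),
                session=row.session,
                signal=signal,
                activity_class=row.activity_class,
                sleep_class=row.sleep_class,
            )
        )
    return records
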