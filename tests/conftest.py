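"""Shared fixtures: small cohorts and drive sets built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from acticam.cohort import (
    ACTIVITY_CLASSES,
    SLEEP_CLASSES,
    CohortConfig,
    MovementModelParams,
    ParticipantProfile,
)
from acticam.prep import DriveRecord, build_drive_records
from acticam.signals import AccelerometrySignal


def smoke_cells(per_cell: int = 2) -> dict:
    return {(a, s): per_cell for a in ACTIVITY_CLASSES for s in SLEEP_CLASSES}


def smoke_cohort_config(effect: float, seed: int = 11) -> CohortConfig:
    """The scaled-down study: 8 participants, 2 experimental days, 2-min drives."""
    return CohortConfig(
        cell_counts=smoke_cells(2),
        seed=seed,
        effect_size_activity=effect,
        effect_size_sleep=effect,
        drive_duration=120.0,
        days=2,
        drives_per_day=2,
    )


def quiet_profile(**overrides) -> ParticipantProfile:
    defaults = dict(
        participant_id="P000",
        activity_class="sitting",
        sleep_class="sleep_9h",
        baseline_thigh_pitch=0.0,
        baseline_thigh_roll=0.0,
    )
    defaults.update(overrides)
    return ParticipantProfile(**defaults)


def silent_params() -> MovementModelParams:
    return MovementModelParams(
        pedal_event_rate=0.0,
        pedal_event_amplitude=0.0,
        pedal_event_amplitude_sd=0.0,
        postural_shift_rate=0.0,
        inactivity_bout_probability=0.0,
        noise_sd=0.0,
    )


def make_drive(n: int = 600, seed: int = 0, participant: str = "P001", day: int = 1, session: str = "pre_shift",
               activity: str = "sitting", sleep: str = "sleep_9h", sample_rate: float = 20.0) -> DriveRecord:
    rng = np.random.default_rng(seed)
    data = np.clip(rng.normal(0.0, 0.1, (n, 3)) + [0.0, 0.0, 1.0], -4, 4)
    signal = AccelerometrySignal(start_time=np.datetime64("2022-03-07T08:10:00"), sample_rate=sample_rate, data=data)
    return DriveRecord(
        participant_id=participant, day=day, session=session, signal=signal,
        activity_class=activity, sleep_class=sleep,
    )


@pytest.fixture(scope="session")
def smoke_drives_null():
    """Drives for the zero-effect cohort at smoke scale (classes identical)."""
    return build_drive_records(smoke_cohort_config(effect=0.0))


@pytest.fixture(scope="session")
def smoke_drives_strong():
    """Drives for the strongly separated cohort at smoke scale."""
    return build_drive_records(smoke_cohort_config(effect=3.0))
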