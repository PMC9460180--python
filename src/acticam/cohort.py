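"""Synthetic 2x2 cohort generator: participants, per-drive accelerometry, metadata.

The generator emulates a laboratory protocol in which participants are
randomized to one of four cells crossing an activity factor (remaining
seated through a simulated workday vs breaking up sitting with short
treadmill walks) with a sleep-opportunity factor (9-h vs 5-h time in bed),
and complete two 20-min simulated drives per experimental day (pre- and
post-shift) for five days, wearing a 20 Hz thigh accelerometer.

The per-drive signal model is a gravity baseline set by thigh posture, plus
pedal-movement bursts (damped oscillations, predominantly on the
longitudinal axis), slow postural-shift ramps that re-project the 1 g
vector, and additive sensor noise.  Class structure enters through two
continuous effect sizes: the activity factor shifts the resting thigh pitch
and the postural-shift rate, while the sleep factor trades movement
frequency against movement amplitude and abruptness (short sleep: sparse,
large, rapid bursts separated by quiet spells; full sleep: frequent smaller
movements).  At effect size zero the class-conditional distributions are
identical by construction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .signals import G_RANGE, AccelerometrySignal, write_activpal_csv

ACTIVITY_CLASSES = ("sitting", "breaking_up_sitting")
SLEEP_CLASSES = ("sleep_9h", "sleep_5h")
SESSIONS = ("pre_shift", "post_shift")

#: Table-style default cell sizes (activity x sleep).
DEFAULT_CELL_COUNTS = {
    ("sitting", "sleep_9h"): 22,
    ("sitting", "sleep_5h"): 22,
    ("breaking_up_sitting", "sleep_9h"): 20,
    ("breaking_up_sitting", "sleep_5h"): 20,
}

# Ground-truth metadata targets: mean total sleep time per night (h) and
# daily step count per class, matching the magnitudes the protocol produces.
SLEEP_META = {"sleep_9h": (8.0, 40 / 60), "sleep_5h": (4.0 + 34 / 60, 18 / 60)}
STEP_META = {"sitting": (1231.0, 661.0), "breaking_up_sitting": (7016.0, 742.0)}

#: First experimental day of the simulated protocol (arbitrary fixed date).
PROTOCOL_START = np.datetime64("2022-03-07")
SESSION_START = {"pre_shift": np.timedelta64(8 * 60 + 10, "m"), "post_shift": np.timedelta64(17 * 60 + 30, "m")}


@dataclass
class CohortConfig:
    cell_counts: dict = field(default_factory=lambda: dict(DEFAULT_CELL_COUNTS))
    seed: int = 0
    effect_size_activity: float = 1.0
    effect_size_sleep: float = 1.0
    sample_rate: float = 20.0
    drive_duration: float = 1200.0
    days: int = 5
    drives_per_day: int = 2

    def __post_init__(self) -> None:
        for cell, count in self.cell_counts.items():
            act, slp = cell
            if act not in ACTIVITY_CLASSES or slp not in SLEEP_CLASSES:
                raise ValueError(f"unknown cohort cell {cell}")
            if count < 0:
                raise ValueError(f"cell count for {cell} must be non-negative")
        if self.sample_rate <= 0 or self.drive_duration <= 0:
            raise ValueError("sample_rate and drive_duration must be positive")
        if self.effect_size_activity < 0 or self.effect_size_sleep < 0:
            raise ValueError("effect sizes must be non-negative")
        if self.days < 1 or self.drives_per_day < 1 or self.drives_per_day > len(SESSIONS):
            raise ValueError("days must be >= 1 and drives_per_day in {1, 2}")

    @property
    def n_participants(self) -> int:
        return sum(self.cell_counts.values())


@dataclass
class MovementModelParams:
    """Class-neutral movement model; rates in events/min, amplitudes in g."""

    pedal_event_rate: float = 8.0
    pedal_event_amplitude: float = 0.6
    pedal_event_amplitude_sd: float = 0.2
    pedal_event_duration: float = 0.8
    postural_shift_rate: float = 0.5
    postural_shift_angle_change: float = 8.0
    inactivity_bout_probability: float = 0.3
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "pedal_event_rate",
            "pedal_event_amplitude_sd",
            "pedal_event_duration",
            "postural_shift_rate",
            "postural_shift_angle_change",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.inactivity_bout_probability <= 1.0:
            raise ValueError("inactivity_bout_probability must be in [0, 1]")
        # keep 1 g baseline + typical burst within the +-4 g device range
        if not 0.0 <= self.pedal_event_amplitude <= G_RANGE - 1.0:
            raise ValueError("pedal_event_amplitude must be in [0, 3] g to keep the baseline in range")


@dataclass
class ParticipantProfile:
    participant_id: str
    activity_class: str
    sleep_class: str
    baseline_thigh_pitch: float  # degrees; 0 = horizontal thigh
    baseline_thigh_roll: float = 0.0
    event_rate_multiplier: float = 1.0
    amplitude_multiplier: float = 1.0
    noise_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.activity_class not in ACTIVITY_CLASSES or self.sleep_class not in SLEEP_CLASSES:
            raise ValueError("profile classes must come from the two binary factors")
        if min(self.event_rate_multiplier, self.amplitude_multiplier, self.noise_multiplier) <= 0:
            raise ValueError("individual multipliers must be positive")


@dataclass
class TTestReport:
    statistic: float
    df: float
    p_value: float
    significant: bool
    group_means: tuple[float, float]


def gravity_projection(pitch_deg: float, roll_deg: float):
    """Project the 1 g gravity vector onto body-fixed axes for a given posture.

    Convention: x along the thigh axis, y mediolateral, z perpendicular to the
    anterior thigh surface.  A horizontal thigh with the device facing up
    (pitch 0, roll 0) reads (0, 0, 1); a vertical thigh reads (1, 0, 0).
    """
    p = np.deg2rad(pitch_deg)
    r = np.deg2rad(roll_deg)
    return np.sin(p), np.cos(p) * np.sin(r), np.cos(p) * np.cos(r)


def class_modulated_params(
    base: MovementModelParams, activity_class: str, sleep_class: str, effect_activity: float, effect_sleep: float
) -> MovementModelParams:
    """Apply the two class factors to the neutral movement model.

    All modulations are multiplicative and reduce to the identity at effect
    size zero, so a zero-effect cohort has class-identical signal
    distributions by construction.
    """
    params = replace(base)
    if effect_activity > 0:
        shift_gain = 1.0 + 0.8 * effect_activity
        if activity_class == "sitting":
            params.postural_shift_rate = base.postural_shift_rate * shift_gain
        else:
            params.postural_shift_rate = base.postural_shift_rate / shift_gain
    if effect_sleep == 0:
        return params

    rate_gain = 1.0 + 0.6 * effect_sleep
    amp_gain = 1.0 + 0.8 * effect_sleep
    p0 = base.inactivity_bout_probability
    if sleep_class == "sleep_5h":
        # sparse, large, abrupt movements separated by quiet spells
        params.pedal_event_rate = base.pedal_event_rate / rate_gain
        params.pedal_event_amplitude = min(base.pedal_event_amplitude * amp_gain, G_RANGE - 1.0)
        params.pedal_event_duration = base.pedal_event_duration / (1.0 + 0.5 * effect_sleep)
        params.inactivity_bout_probability = 1.0 - (1.0 - p0) ** (1.0 + effect_sleep)
    else:
        # frequent movements of unchanged size with little quiet time; the
        # amplitude is deliberately left at baseline so separability grows
        # monotonically with effect size instead of sinking both classes
        # into the noise floor
        params.pedal_event_rate = base.pedal_event_rate * rate_gain
        params.inactivity_bout_probability = p0 / (1.0 + effect_sleep)
    return params


def baseline_pitch_mean(activity_class: str, effect_activity: float) -> float:
    """Class-mean resting thigh pitch (deg) while seated at the simulator."""
    delta = 6.0 * effect_activity
    return 15.0 + delta if activity_class == "sitting" else 15.0 - delta


def generate_cohort(config: CohortConfig) -> tuple[list[ParticipantProfile], pd.DataFrame]:
    """Draw participant profiles and cohort metadata for every cell.

    Returns the profiles (one per participant, cell membership matching
    ``config.cell_counts``) and a metadata frame with each participant's
    simulated mean total sleep time per night (h) and mean daily step count.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    profiles: list[ParticipantProfile] = []
    meta_rows = []
    index = 0
    for act in ACTIVITY_CLASSES:
        for slp in SLEEP_CLASSES:
            count = config.cell_counts.get((act, slp), 0)
            for _ in range(count):
                index += 1
                pid = f"P{index:03d}"
                profiles.append(
                    ParticipantProfile(
                        participant_id=pid,
                        activity_class=act,
                        sleep_class=slp,
                        baseline_thigh_pitch=rng.normal(baseline_pitch_mean(act, config.effect_size_activity), 5.0),
                        baseline_thigh_roll=rng.normal(0.0, 4.0),
                        event_rate_multiplier=float(rng.lognormal(0.0, 0.15)),
                        amplitude_multiplier=float(rng.lognormal(0.0, 0.15)),
                        noise_multiplier=float(rng.lognormal(0.0, 0.2)),
                    )
                )
                sleep_mu, sleep_sd = SLEEP_META[slp]
                step_mu, step_sd = STEP_META[act]
                meta_rows.append(
                    {
                        "participant_id": pid,
                        "activity_class": act,
                        "sleep_class": slp,
                        "mean_sleep_h": max(rng.normal(sleep_mu, sleep_sd), 0.1),
                        "mean_daily_steps": int(max(round(rng.normal(step_mu, step_sd)), 0)),
                    }
                )
    columns = ["participant_id", "activity_class", "sleep_class", "mean_sleep_h", "mean_daily_steps"]
    metadata = pd.DataFrame(meta_rows, columns=columns)
    return profiles, metadata


def participant_params(profile: ParticipantProfile, config: CohortConfig, base: MovementModelParams) -> MovementModelParams:
    """Class-modulated then individually scaled movement parameters."""
    params = class_modulated_params(
        base, profile.activity_class, profile.sleep_class, config.effect_size_activity, config.effect_size_sleep
    )
    params.pedal_event_rate *= profile.event_rate_multiplier
    params.pedal_event_amplitude = min(params.pedal_event_amplitude * profile.amplitude_multiplier, G_RANGE - 1.0)
    params.noise_sd *= profile.noise_multiplier
    return params


def drive_seed(base_seed: int, participant_id: str, day: int, session: str) -> int:
    """Stable per-drive seed below 2**31, derived from the cohort seed."""
    digest = hashlib.sha256(f"{base_seed}:{participant_id}:{day}:{session}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def drive_start_time(day: int, session: str) -> np.datetime64:
    return (PROTOCOL_START + np.timedelta64(day - 1, "D") + SESSION_START[session]).astype("datetime64[ms]")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def generate_drive_signal(
    profile: ParticipantProfile,
    params: MovementModelParams,
    seed: int,
    sample_rate: float = 20.0,
    duration: float = 1200.0,
    start_time: np.datetime64 | None = None,
) -> AccelerometrySignal:
    """Simulate one drive's triaxial accelerometry.

    The signal is the gravity projection of a slowly varying thigh posture,
    plus Poisson pedal bursts and additive Gaussian noise, clipped to the
    +-4 g device range.  The per-drive event count is exactly
    Poisson(rate x duration): inactivity bouts redistribute events away from
    quiet minutes rather than deleting them.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(sample_rate * duration))
    t = np.arange(n) / sample_rate

    # -- posture track (degrees) ------------------------------------------
    pitch = np.full(n, profile.baseline_thigh_pitch)
    roll = np.full(n, profile.baseline_thigh_roll)
    if params.postural_shift_rate > 0:
        # per-drive settling offset plus smooth shift ramps
        pitch += rng.normal(0.0, params.postural_shift_angle_change / 2.0)
        roll += rng.normal(0.0, params.postural_shift_angle_change / 4.0)
        n_shifts = rng.poisson(params.postural_shift_rate * duration / 60.0)
        ramp_s = 2.0
        for _ in range(n_shifts):
            t0 = rng.uniform(0.0, duration)
            pitch += rng.normal(0.0, params.postural_shift_angle_change) * _smoothstep((t - t0) / ramp_s)
            roll += rng.normal(0.0, params.postural_shift_angle_change / 2.0) * _smoothstep((t - t0) / ramp_s)

    gx, gy, gz = gravity_projection(pitch, roll)
    data = np.stack([gx, gy, gz], axis=1)

    # -- pedal-movement bursts --------------------------------------------
    event_times = draw_pedal_events(rng, params, duration)
    if len(event_times) > 0:
        for t0 in event_times:
            # smooth sin^2-enveloped oscillation spanning the full event;
            # shorter durations give the same amplitude a more abrupt onset
            dur = max(params.pedal_event_duration, 2.0 / sample_rate)
            amp = abs(rng.normal(params.pedal_event_amplitude, params.pedal_event_amplitude_sd))
            freq = rng.uniform(1.0, 2.5)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            sy = 0.35 * rng.choice((-1.0, 1.0))
            sz = 0.45 * rng.choice((-1.0, 1.0))
            i0 = int(np.ceil(t0 * sample_rate))
            i1 = min(int(np.ceil((t0 + dur) * sample_rate)), n)
            if i0 >= n:
                continue
            trel = t[i0:i1] - t0
            envelope = np.sin(np.pi * trel / dur) ** 2
            wave = amp * envelope * np.sin(2.0 * np.pi * freq * trel + phase)
            data[i0:i1, 0] += wave
            data[i0:i1, 1] += sy * wave
            data[i0:i1, 2] += sz * wave

    if params.noise_sd > 0:
        data += rng.normal(0.0, params.noise_sd, data.shape)

    np.clip(data, -G_RANGE, G_RANGE, out=data)
    if start_time is None:
        start_time = drive_start_time(1, "pre_shift")
    return AccelerometrySignal(start_time=start_time, sample_rate=sample_rate, data=data)


def draw_pedal_events(rng: np.random.Generator, params: MovementModelParams, duration: float) -> np.ndarray:
    """Pedal-event onset times for one drive.

    The count is exactly Poisson(rate x duration); inactivity bouts only
    restrict *where* events land (active minutes), preserving the marginal
    count distribution while producing quiet spells.
    """
    n_events = int(rng.poisson(params.pedal_event_rate * duration / 60.0))
    if n_events == 0:
        return np.empty(0)
    n_minutes = int(np.ceil(duration / 60.0))
    active = rng.random(n_minutes) >= params.inactivity_bout_probability
    if not active.any():
        active[:] = True
    active_idx = np.flatnonzero(active)
    minutes = rng.choice(active_idx, size=n_events)
    times = (minutes + rng.random(n_events)) * 60.0
    return np.sort(times[times < duration])


# ---------------------------------------------------------------------------
# Cohort-level I/O and verification
# ---------------------------------------------------------------------------


def drive_schedule(config: CohortConfig) -> list[tuple[int, str]]:
    return [(day, SESSIONS[s]) for day in range(1, config.days + 1) for s in range(config.drives_per_day)]


def write_drive_manifest(profiles: list[ParticipantProfile], config: CohortConfig, path) -> pd.DataFrame:
    """One row per (participant, day, session) with the drive start timestamp."""
    rows = [
        {
            "participant_id": p.participant_id,
            "activity_class": p.activity_class,
            "sleep_class": p.sleep_class,
            "day": day,
            "session": session,
            "drive_start": pd.Timestamp(drive_start_time(day, session)).isoformat(timespec="milliseconds"),
        }
        for p in profiles
        for day, session in drive_schedule(config)
    ]
    columns = ["participant_id", "activity_class", "sleep_class", "day", "session", "drive_start"]
    manifest = pd.DataFrame(rows, columns=columns)
    manifest.to_csv(path, index=False)
    return manifest


def simulate_cohort_to_dir(
    config: CohortConfig, out_dir, base_params: MovementModelParams | None = None, write_signals: bool = True
) -> pd.DataFrame:
    """Generate the full cohort and write manifest, metadata and per-drive CSVs."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = base_params or MovementModelParams()
    profiles, metadata = generate_cohort(config)
    metadata.to_csv(out / "metadata.csv", index=False)
    manifest = write_drive_manifest(profiles, config, out / "manifest.csv")
    if write_signals:
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
                write_activpal_csv(signal, out / f"{p.participant_id}_E{day}_{session}.csv")
    return manifest


def verify_ground_truth(metadata: pd.DataFrame, alpha: float = 0.05) -> dict[str, TTestReport]:
    """Welch t-tests confirming the cohort's ground-truth labels.

    Compares total sleep time between the 9-h and 5-h classes and daily step
    count between the sitting and breaking-up-sitting classes.
    """
    reports = {}
    for key, column, factor, groups in (
        ("sleep", "mean_sleep_h", "sleep_class", SLEEP_CLASSES),
        ("steps", "mean_daily_steps", "activity_class", ACTIVITY_CLASSES),
    ):
        a = metadata.loc[metadata[factor] == groups[0], column].to_numpy(dtype=float)
        b = metadata.loc[metadata[factor] == groups[1], column].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"ground-truth t-test for {key!r} needs >= 2 participants per group")
        result = stats.ttest_ind(a, b, equal_var=False)
        reports[key] = TTestReport(
            statistic=float(result.statistic),
            df=float(result.df),
            p_value=float(result.pvalue),
            significant=bool(result.pvalue < alpha),
            group_means=(float(a.mean()), float(b.mean())),
        )
    return reports
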