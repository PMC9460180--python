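"""Uniformly sampled triaxial accelerometry in g units, plus its CSV dialect.

The on-disk format mirrors raw thigh-monitor exports: a header ``time,x,y,z``,
ISO-8601 millisecond timestamps at fixed spacing (50 ms at 20 Hz), and
acceleration in g to six decimal places.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

G_RANGE = 4.0  # device sampling range is +-4 g


@dataclass
class AccelerometrySignal:
    """A (N, 3) array of x/y/z acceleration sampled uniformly at ``sample_rate`` Hz."""

    start_time: np.datetime64
    sample_rate: float
    data: np.ndarray  # shape (N, 3), g units

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("signal data must have shape (N, 3)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.start_time = np.datetime64(self.start_time, "ms")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.data[:, 2]

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    def timestamps(self) -> np.ndarray:
        step_ms = 1000.0 / self.sample_rate
        offsets = np.round(np.arange(len(self)) * step_ms).astype("timedelta64[ms]")
        return self.start_time + offsets

    def time_to_index(self, when: np.datetime64) -> int:
        """Index of the first sample at or after ``when``."""
        delta_ms = (np.datetime64(when, "ms") - self.start_time) / np.timedelta64(1, "ms")
        return int(np.ceil(delta_ms * self.sample_rate / 1000.0 - 1e-9))


def write_activpal_csv(signal: AccelerometrySignal, path) -> None:
    """Write ``time,x,y,z`` rows; round-trips with :func:`read_accel_csv` to 1e-6 g."""
    frame = pd.DataFrame(
        {
            "time": pd.DatetimeIndex(signal.timestamps()).strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3],
            "x": signal.x,
            "y": signal.y,
            "z": signal.z,
        }
    )
    frame.to_csv(path, index=False, float_format="%.6f")


def read_accel_csv(path, spacing_tolerance: float = 1e-3) -> AccelerometrySignal:
    """Parse a raw accelerometry CSV into an :class:`AccelerometrySignal`.

    Rejects files with missing channels, non-monotone timestamps, or spacing
    that deviates from uniformity by more than ``spacing_tolerance`` (as a
    fraction of the median step).
    """
    frame = pd.read_csv(path)
    missing = {"time", "x", "y", "z"} - set(frame.columns)
    if missing:
        raise ValueError(f"accelerometry CSV missing column(s): {sorted(missing)}")
    if len(frame) == 0:
        raise ValueError("accelerometry CSV contains no samples")
    times = pd.to_datetime(frame["time"]).to_numpy().astype("datetime64[ms]")
    data = frame[["x", "y", "z"]].to_numpy(dtype=np.float64)
    if len(times) == 1:
        return AccelerometrySignal(start_time=times[0], sample_rate=20.0, data=data)
    steps = np.diff(times) / np.timedelta64(1, "ms")
    if np.any(steps <= 0):
        raise ValueError("timestamps are not strictly increasing")
    step = float(np.median(steps))
    if np.any(np.abs(steps - step) > spacing_tolerance * step + 0.5):
        raise ValueError("timestamp spacing is not uniform within tolerance")
    return AccelerometrySignal(start_time=times[0], sample_rate=1000.0 / step, data=data)
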