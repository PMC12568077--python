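"""In-memory containers for IMU recordings, windows, masks, bouts and strides.

Conventions used throughout the package:

* sample indices are 0-based;
* intervals (bouts, calibration segments) are half-open ``[start, end)``;
* acceleration is in m/s^2, angular velocity in deg/s;
* in the shank frame the axis order is x = anteroposterior,
  y = mediolateral, z = vertical (gravity along +z).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Canonical 7-class activity taxonomy (harmonized label set).
CLASSES = (
    "static",
    "walking",
    "running",
    "cycling",
    "stair_ascent",
    "stair_descent",
    "other",
)

#: Sentinel label for samples that carry no usable activity label.
UNLABELED = "unlabeled"

SENSOR_LOCATIONS = ("ankle", "proximal_shank")
SIDES = ("left", "right", "unknown")


@dataclass
class RecordingMeta:
    """Identity and placement of one IMU recording."""

    subject_id: str
    sensor_location: str = "ankle"
    sampling_rate_hz: float = 100.0
    side: str = "unknown"

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if self.sensor_location not in SENSOR_LOCATIONS:
            raise ValueError(f"unknown sensor_location {self.sensor_location!r}")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class ImuRecording:
    """Tri-axial accelerometer + gyroscope time series.

    ``frame`` is ``"raw"`` for as-recorded sensor axes and ``"shank"`` once
    calibrated (gravity along +z, anteroposterior along +x).
    """

    time_s: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    meta: RecordingMeta
    frame: str = "raw"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.time_s)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"accel {self.accel.shape} and gyro {self.gyro.shape} must both be ({n}, 3)"
            )
        if self.frame not in ("raw", "shank"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if n >= 2:
            dt = np.diff(self.time_s)
            nominal = 1.0 / self.meta.sampling_rate_hz
            if np.any(np.abs(dt - nominal) > 0.01 * nominal + 1e-12):
                raise ValueError("time step deviates more than 1% from 1/sampling_rate")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def rate(self) -> float:
        return self.meta.sampling_rate_hz

    def channels(self) -> np.ndarray:
        """Return the (N, 6) channel matrix in order ax, ay, az, gx, gy, gz."""
        return np.hstack([self.accel, self.gyro])


@dataclass
class LabeledRecording:
    """An :class:`ImuRecording` plus per-sample activity labels.

    ``retained`` marks samples that survive label harmonization / edge
    trimming; windowing never crosses a non-retained sample, so marking a
    stretch non-retained is equivalent to splitting the recording there.
    """

    recording: ImuRecording
    labels: np.ndarray
    retained: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        n = self.recording.n_samples
        if len(self.labels) != n:
            raise ValueError(f"labels length {len(self.labels)} != n_samples {n}")
        if self.retained is None:
            self.retained = np.ones(n, dtype=bool)
        else:
            self.retained = np.asarray(self.retained, dtype=bool)
            if len(self.retained) != n:
                raise ValueError("retained mask length mismatch")

    @property
    def n_samples(self) -> int:
        return self.recording.n_samples

    def replace(self, **kw) -> "LabeledRecording":
        return dataclasses.replace(self, **kw)


@dataclass
class WindowSet:
    """Fixed-length windows cut from one participant's recording(s).

    ``windows`` has shape (W, window_sz, n_channels), channel order
    ax, ay, az, gx, gy, gz. Each window carries a single activity label.
    """

    windows: np.ndarray
    labels: np.ndarray
    starts: np.ndarray
    window_sz: int
    n_channels: int = 6
    sampling_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.starts = np.asarray(self.starts, dtype=int)
        w = len(self.labels)
        if self.windows.size and self.windows.shape != (w, self.window_sz, self.n_channels):
            raise ValueError(
                f"windows shape {self.windows.shape} != ({w}, {self.window_sz}, {self.n_channels})"
            )
        if len(self.starts) != w:
            raise ValueError("starts length mismatch")

    @property
    def n_windows(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            self.windows[idx],
            self.labels[idx],
            self.starts[idx],
            self.window_sz,
            self.n_channels,
            self.sampling_rate_hz,
        )

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        if not sets:
            raise ValueError("cannot concatenate an empty list of WindowSets")
        first = sets[0]
        return WindowSet(
            np.concatenate([s.windows for s in sets]) if any(s.n_windows for s in sets)
            else first.windows,
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.starts for s in sets]),
            first.window_sz,
            first.n_channels,
            first.sampling_rate_hz,
        )


@dataclass
class ScalerParams:
    """Per-channel standardization parameters fitted on walking samples."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != (6,) or self.std.shape != (6,):
            raise ValueError("mean/std must each have 6 entries")
        if np.any(self.std <= 0):
            raise ValueError("std components must be positive")


@dataclass
class GaitMask:
    """Per-sample Boolean walking indicator aligned to a recording."""

    is_walking: np.ndarray
    sampling_rate_hz: float
    provenance: str = "freq"  # "freq" or "ml_model"

    def __post_init__(self) -> None:
        self.is_walking = np.asarray(self.is_walking, dtype=bool)
        if self.provenance not in ("freq", "ml_model", "truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_samples(self) -> int:
        return len(self.is_walking)


@dataclass
class BoutList:
    """Disjoint, sorted, half-open walking intervals in sample units."""

    intervals: list
    min_duration_s: float = 0.0

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"invalid interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("intervals must be disjoint and sorted")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class StrideSet:
    """Heel-strike-delimited strides, each time-normalized to 101 points.

    ``strides`` holds mediolateral angular velocity; ``stride_bounds`` the
    (heel_strike, next_heel_strike) sample index pair of each stride;
    ``heel_strikes`` every detected heel strike; ``bout_ids`` the source bout.
    """

    strides: np.ndarray
    stride_bounds: np.ndarray
    heel_strikes: np.ndarray
    bout_ids: np.ndarray
    midswing_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.strides = np.asarray(self.strides, dtype=float).reshape(-1, 101)
        self.stride_bounds = np.asarray(self.stride_bounds, dtype=int).reshape(-1, 2)
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.bout_ids = np.asarray(self.bout_ids, dtype=int)
        s = len(self.strides)
        if len(self.stride_bounds) != s or len(self.bout_ids) != s:
            raise ValueError("stride_bounds/bout_ids length mismatch")

    @property
    def n_strides(self) -> int:
        return len(self.strides)

    @staticmethod
    def empty() -> "StrideSet":
        return StrideSet(
            np.empty((0, 101)), np.empty((0, 2), dtype=int),
            np.array([], dtype=int), np.array([], dtype=int),
        )

    @staticmethod
    def concatenate(sets: list["StrideSet"]) -> "StrideSet":
        if not sets:
            return StrideSet.empty()
        return StrideSet(
            np.concatenate([s.strides for s in sets]) if sets else np.empty((0, 101)),
            np.concatenate([s.stride_bounds for s in sets]),
            np.concatenate([s.heel_strikes for s in sets]),
            np.concatenate([s.bout_ids for s in sets]),
            np.concatenate([s.midswing_peaks for s in sets]),
        )


@dataclass
class PredictionSet:
    """Window-level class probabilities and argmax labels."""

    probabilities: np.ndarray
    predicted_labels: np.ndarray
    starts: np.ndarray
    window_sz: int
    classes: tuple = CLASSES

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.predicted_labels = np.asarray(self.predicted_labels, dtype=object)
        self.starts = np.asarray(self.starts, dtype=int)
        w = len(self.starts)
        if self.probabilities.shape[0] != w or len(self.predicted_labels) != w:
            raise ValueError("prediction arrays must share their first dimension")
        if self.probabilities.size:
            sums = self.probabilities.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-5):
                raise ValueError("probability rows must sum to 1 within 1e-5")

    @property
    def n_windows(self) -> int:
        return len(self.starts)
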