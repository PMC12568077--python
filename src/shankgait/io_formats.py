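"""Readers and writers for IMU recordings and pipeline artifacts.

Supported inputs: PAMAP2 protocol ``.dat`` files (space-separated, 54
columns, ankle IMU block) and a generic per-sample IMU CSV dialect with
columns ``time_s, ax, ay, az, gx, gy, gz, label``. Outputs (gait masks,
bouts, strides, metric reports) are plain CSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_PAMAP2_LABEL_MAP, RunConfig
from .containers import (
    UNLABELED,
    BoutList,
    GaitMask,
    ImuRecording,
    LabeledRecording,
    RecordingMeta,
    StrideSet,
)

PAMAP2_N_COLUMNS = 54
# 0-based column indices into a PAMAP2 protocol row.
_COL_TIME = 0
_COL_ACTIVITY = 1
# Ankle IMU block: 1-based cols 38-54; +/-16 g accelerometer at 39-41,
# gyroscope (rad/s) at 45-47.
_COLS_ANKLE_ACC16 = [38, 39, 40]
_COLS_ANKLE_GYRO = [44, 45, 46]

#: Activity IDs that may appear in PAMAP2 protocol files (0 = transient).
PAMAP2_KNOWN_IDS = frozenset(DEFAULT_PAMAP2_LABEL_MAP)


class FormatError(ValueError):
    """Raised when an input file does not match its declared dialect."""


def _interpolate_short_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap; return a mask of
    samples still inside longer (uninterpolated) gaps."""
    n, k = values.shape
    long_gap = np.zeros(n, dtype=bool)
    isnan = np.isnan(values).any(axis=1)
    if not isnan.any():
        return long_gap
    idx = np.arange(n)
    # locate NaN runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], isnan.view(np.int8), [0]])))
    for start, end in zip(edges[::2], edges[1::2]):
        gap = end - start
        interior = 0 < start and end < n
        if gap <= max_gap and interior:
            for c in range(k):
                values[start:end, c] = np.interp(
                    idx[start:end], [start - 1, end], [values[start - 1, c], values[end, c]]
                )
        else:
            # boundary or long gap: hold neighbor values, mark unusable
            fill = values[end] if start == 0 else values[start - 1]
            values[start:end] = fill
            long_gap[start:end] = True
    return long_gap


def read_pamap2(
    path,
    subject_id: str,
    label_map: dict | None = None,
    max_gap_s: float = 0.2,
) -> LabeledRecording:
    """Read the ankle IMU block of a PAMAP2 protocol ``.dat`` file.

    Returns a 100 Hz recording whose labels are the raw PAMAP2 activity IDs
    (as strings, e.g. ``"4"``); mapping onto the 7-class taxonomy is done by
    :func:`shankgait.preprocess.harmonize_labels`. Wireless-dropout NaNs in
    gaps <= ``max_gap_s`` are linearly interpolated; samples inside longer
    gaps are marked non-retained, which splits the recording for windowing.
    Gyroscope readings are converted from rad/s to deg/s.
    """
    path = Path(path)
    known = frozenset(label_map) if label_map is not None else PAMAP2_KNOWN_IDS
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != PAMAP2_N_COLUMNS:
                raise FormatError(
                    f"{path.name}:{lineno}: expected {PAMAP2_N_COLUMNS} columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts)
    data = np.array(rows, dtype=float)
    activity = data[:, _COL_ACTIVITY].astype(int)
    unknown = set(activity) - set(known)
    if unknown:
        raise FormatError(
            f"{path.name}: unknown PAMAP2 activity ID(s) {sorted(unknown)}"
        )
    rate = 100.0
    accel = data[:, _COLS_ANKLE_ACC16].copy()
    gyro = np.degrees(data[:, _COLS_ANKLE_GYRO])
    max_gap = int(round(max_gap_s * rate))
    sensor = np.hstack([accel, gyro])
    long_gap = _interpolate_short_gaps(sensor, max_gap)
    accel, gyro = sensor[:, :3], sensor[:, 3:]
    time_s = np.arange(len(data)) / rate
    meta = RecordingMeta(subject_id=subject_id, sensor_location="ankle",
                         sampling_rate_hz=rate)
    rec = ImuRecording(time_s, accel, gyro, meta)
    labels = np.array([str(a) for a in activity], dtype=object)
    return LabeledRecording(rec, labels, retained=~long_gap)


def read_imu_csv(path, meta: RecordingMeta) -> LabeledRecording:
    """Read a generic per-sample IMU CSV (time_s, ax..az m/s^2, gx..gz deg/s,
    label). Empty labels become ``"unlabeled"``. Emits a warning when
    static-labeled rows have a median acceleration norm outside [5, 15]
    m/s^2 (likely a g-units file)."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    required = ["time_s", "ax", "ay", "az", "gx", "gy", "gz", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time_s is not strictly increasing")
    labels = np.array(
        [str(v) if str(v).strip() else UNLABELED for v in df["label"]], dtype=object
    )
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    static = labels == "static"
    if static.any():
        med = float(np.median(np.linalg.norm(accel[static], axis=1)))
        if not 5.0 <= med <= 15.0:
            warnings.warn(
                f"median static acceleration norm {med:.2f} m/s^2 outside "
                "[5, 15]; file may be in g units",
                UserWarning,
            )
    rec = ImuRecording(t, accel, gyro, meta)
    return LabeledRecording(rec, labels)


def write_imu_csv(lrec: LabeledRecording, path) -> None:
    """Write a labeled recording in the generic IMU CSV dialect."""
    rec = lrec.recording
    df = pd.DataFrame(
        {
            "time_s": rec.time_s,
            "ax": rec.accel[:, 0], "ay": rec.accel[:, 1], "az": rec.accel[:, 2],
            "gx": rec.gyro[:, 0], "gy": rec.gyro[:, 1], "gz": rec.gyro[:, 2],
            "label": [("" if l == UNLABELED else l) for l in lrec.labels],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def write_gait_mask(mask: GaitMask, path) -> None:
    pd.DataFrame(
        {"sample_index": np.arange(mask.n_samples),
         "is_walking": mask.is_walking.astype(int)}
    ).to_csv(path, index=False)


def read_gait_mask(path, sampling_rate_hz: float = 100.0,
                   provenance: str = "freq") -> GaitMask:
    df = pd.read_csv(path)
    order = np.argsort(df["sample_index"].to_numpy())
    return GaitMask(df["is_walking"].to_numpy()[order].astype(bool),
                    sampling_rate_hz, provenance)


def write_bouts(bouts: BoutList, path) -> None:
    pd.DataFrame(
        {"start_sample": [s for s, _ in bouts.intervals],
         "end_sample": [e for _, e in bouts.intervals]}
    ).to_csv(path, index=False)


def read_bouts(path) -> BoutList:
    df = pd.read_csv(path)
    return BoutList(list(zip(df["start_sample"].astype(int),
                             df["end_sample"].astype(int))))


def write_strides(strides: StrideSet, path) -> None:
    """Strides as CSV: bout id, heel-strike bounds, then 101 value columns."""
    cols = {"bout_id": strides.bout_ids,
            "hs_start": strides.stride_bounds[:, 0],
            "hs_end": strides.stride_bounds[:, 1]}
    for j in range(101):
        cols[f"p{j:03d}"] = strides.strides[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def read_strides(path) -> StrideSet:
    df = pd.read_csv(path)
    vals = df[[f"p{j:03d}" for j in range(101)]].to_numpy(dtype=float)
    bounds = df[["hs_start", "hs_end"]].to_numpy(dtype=int)
    hs = np.unique(bounds) if len(bounds) else np.array([], dtype=int)
    return StrideSet(vals, bounds, hs, df["bout_id"].to_numpy(dtype=int))


def write_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def load_config(path) -> RunConfig:
    return RunConfig.load(path)


def save_config(cfg: RunConfig, path) -> None:
    cfg.save(path)
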