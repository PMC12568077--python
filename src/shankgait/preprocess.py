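"""Preprocessing: calibration, resampling, label harmonization, windowing,
static filtering and participant-specific scaling.

The pipeline order mirrors the published procedure: calibrate to the shank
frame using quiet standing + a walking section, standardize units, harmonize
labels onto the 7-class taxonomy, trim activity edges, cut 5 s / 50%-overlap
windows per contiguous single-label run, gate static windows at 1 m/s^2 RMS,
and standardize channels with a per-participant scaler fitted on walking.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal as sp_signal
from scipy.spatial.transform import Rotation
from scipy.stats import skew

from .config import RunConfig
from .containers import (
    CLASSES,
    UNLABELED,
    ImuRecording,
    LabeledRecording,
    ScalerParams,
    WindowSet,
)

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    pass


def _rotation_to_vertical(mean_accel: np.ndarray) -> Rotation:
    """Minimal rotation sending the measured gravity direction onto +z."""
    u = mean_accel / np.linalg.norm(mean_accel)
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [u])
    return rot


def compute_calibration(
    rec: ImuRecording,
    standing: tuple,
    walking: tuple,
    quiet_rms_limit: float = 1.0,
) -> Rotation:
    """Derive the sensor-to-shank rotation from calibration intervals.

    Step 1 rotates the mean quiet-standing acceleration onto +z (gravity
    vertical). Step 2 rotates about the vertical so the first horizontal
    principal direction of the walking acceleration lies along +x
    (anteroposterior); the sign of +x is chosen so that the skewness of the
    anteroposterior walking acceleration is positive (forward-progression
    convention, ties toward +x). ``standing`` and ``walking`` are half-open
    sample intervals.
    """
    s0, s1 = standing
    w0, w1 = walking
    stand_acc = rec.accel[s0:s1]
    if len(stand_acc) < 2:
        raise CalibrationError("standing interval too short")
    norms = np.linalg.norm(stand_acc, axis=1)
    if float(np.sqrt(np.mean((norms - norms.mean()) ** 2))) > quiet_rms_limit:
        raise CalibrationError("standing interval not quiet (accel RMS > limit)")
    r1 = _rotation_to_vertical(stand_acc.mean(axis=0))

    walk_acc = r1.apply(rec.accel[w0:w1])
    horiz = walk_acc[:, :2] - walk_acc[:, :2].mean(axis=0)
    cov = horiz.T @ horiz / max(len(horiz), 1)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]  # first horizontal principal direction
    ap = horiz @ v
    if skew(ap) < 0:
        v = -v
    yaw = np.arctan2(v[1], v[0])
    r2 = Rotation.from_rotvec([0.0, 0.0, -yaw])
    return r2 * r1


def calibrate_to_shank_frame(
    rec: ImuRecording,
    standing: tuple,
    walking: tuple,
    quiet_rms_limit: float = 1.0,
) -> ImuRecording:
    """Rigidly rotate accelerometer and gyroscope into the shank frame
    (see :func:`compute_calibration` for the two-step alignment)."""
    rot = compute_calibration(rec, standing, walking, quiet_rms_limit)
    return ImuRecording(
        rec.time_s.copy(),
        rot.apply(rec.accel),
        rot.apply(rec.gyro),
        rec.meta,
        frame="shank",
    )


def downsample(rec: ImuRecording, target_rate_hz: float) -> ImuRecording:
    """Anti-alias low-pass (cutoff 0.4 x target rate) then decimate.

    The source rate must be an integer multiple of the target rate.
    """
    ratio = rec.rate / target_rate_hz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"source rate {rec.rate} Hz is not an integer multiple of "
            f"{target_rate_hz} Hz"
        )
    if factor == 1:
        return rec
    sos = sp_signal.butter(8, 0.4 * target_rate_hz, btype="low",
                           fs=rec.rate, output="sos")
    n_out = rec.n_samples // factor
    acc = sp_signal.sosfiltfilt(sos, rec.accel, axis=0)[::factor][:n_out]
    gyr = sp_signal.sosfiltfilt(sos, rec.gyro, axis=0)[::factor][:n_out]
    meta = type(rec.meta)(rec.meta.subject_id, rec.meta.sensor_location,
                          target_rate_hz, rec.meta.side)
    t = np.arange(n_out) / target_rate_hz + rec.time_s[0]
    return ImuRecording(t, acc, gyr, meta, frame=rec.frame)


def downsample_labeled(lrec: LabeledRecording, target_rate_hz: float) -> LabeledRecording:
    rec = downsample(lrec.recording, target_rate_hz)
    factor = int(round(lrec.recording.rate / target_rate_hz))
    n = rec.n_samples
    return LabeledRecording(rec, lrec.labels[::factor][:n],
                            lrec.retained[::factor][:n])


def harmonize_labels(lrec: LabeledRecording, mapping: dict) -> LabeledRecording:
    """Map raw labels onto the 7-class taxonomy.

    ``mapping`` maps every raw label present either to one of the seven
    classes or to ``"drop"``. Dropped and unlabeled samples become
    ``"unlabeled"`` with ``retained=False`` (removal realized as a mask).
    """
    mapping = {str(k): v for k, v in mapping.items()}
    valid_targets = set(CLASSES) | {"drop", UNLABELED}
    bad_targets = set(mapping.values()) - valid_targets
    if bad_targets:
        raise ValueError(f"mapping targets {sorted(bad_targets)} are not classes")
    labels = np.empty(lrec.n_samples, dtype=object)
    retained = lrec.retained.copy()
    for i, raw in enumerate(lrec.labels):
        raw = str(raw)
        if raw in CLASSES:
            labels[i] = raw
            continue
        if raw == UNLABELED:
            labels[i] = UNLABELED
            retained[i] = False
            continue
        if raw not in mapping:
            raise KeyError(f"no mapping for raw label {raw!r}")
        tgt = mapping[raw]
        if tgt in ("drop", UNLABELED):
            labels[i] = UNLABELED
            retained[i] = False
        else:
            labels[i] = tgt
    return LabeledRecording(lrec.recording, labels, retained)


def _label_runs(lrec: LabeledRecording):
    """Yield (start, end, label) over maximal contiguous retained runs of a
    single label (half-open)."""
    n = lrec.n_samples
    i = 0
    while i < n:
        if not lrec.retained[i] or lrec.labels[i] == UNLABELED:
            i += 1
            continue
        j = i + 1
        while j < n and lrec.retained[j] and lrec.labels[j] == lrec.labels[i]:
            j += 1
        yield i, j, lrec.labels[i]
        i = j


def trim_activity_edges(lrec: LabeledRecording, n_trim: int = 500) -> LabeledRecording:
    """Drop the first and last ``n_trim`` samples of each contiguous activity
    run (transitional periods / labeling inaccuracy); runs of length
    <= 2*n_trim are removed entirely."""
    retained = lrec.retained.copy()
    for start, end, _ in _label_runs(lrec):
        if end - start <= 2 * n_trim:
            retained[start:end] = False
        else:
            retained[start:start + n_trim] = False
            retained[end - n_trim:end] = False
    return LabeledRecording(lrec.recording, lrec.labels, retained)


def segment_windows(lrec: LabeledRecording, cfg: RunConfig) -> WindowSet:
    """Cut fixed-length sliding windows per contiguous single-label run.

    Windows never span label boundaries or removed samples; each window
    carries its run's label. A run shorter than one window contributes no
    windows (logged).
    """
    rate = lrec.recording.rate
    window_sz = int(round(cfg.window_seconds * rate))
    hop = int(round(window_sz * (1.0 - cfg.overlap_fraction)))
    if hop < 1:
        raise ValueError("overlap too large: hop must be >= 1 sample")
    chans = lrec.recording.channels()
    wins, labels, starts = [], [], []
    for start, end, label in _label_runs(lrec):
        n = end - start
        if n < window_sz:
            log.debug("run [%d, %d) label %s shorter than one window", start, end, label)
            continue
        for s in range(start, end - window_sz + 1, hop):
            wins.append(chans[s:s + window_sz])
            labels.append(label)
            starts.append(s)
    if wins:
        windows = np.stack(wins)
    else:
        windows = np.empty((0, window_sz, 6))
    return WindowSet(windows, np.array(labels, dtype=object),
                     np.array(starts, dtype=int), window_sz, 6, rate)


def static_window_rms(window: np.ndarray) -> float:
    """RMS of the acceleration-norm deviation from the window's own gravity
    estimate (the mean acceleration norm)."""
    anorm = np.linalg.norm(window[:, :3], axis=1)
    return float(np.sqrt(np.mean((anorm - anorm.mean()) ** 2)))


def filter_static_windows(ws: WindowSet, limit: float = 1.0) -> WindowSet:
    """Keep static-labeled windows only when their RMS acceleration deviation
    is strictly less than ``limit`` (m/s^2); other windows pass through."""
    keep = np.ones(ws.n_windows, dtype=bool)
    for i in range(ws.n_windows):
        if ws.labels[i] == "static" and static_window_rms(ws.windows[i]) >= limit:
            keep[i] = False
    return ws.subset(np.flatnonzero(keep))


def fit_participant_scaler(lrec: LabeledRecording) -> ScalerParams:
    """Per-channel mean/std fitted on the participant's retained walking
    samples only. Channels with std < 1e-8 get scale 1 (degenerate guard)."""
    sel = (lrec.labels == "walking") & lrec.retained
    if not sel.any():
        raise ValueError("scaler requires a walking section for this participant")
    chans = lrec.recording.channels()[sel]
    mean = chans.mean(axis=0)
    std = chans.std(axis=0)
    degenerate = std < 1e-8
    if degenerate.any():
        warnings.warn("degenerate channel(s) in scaler fit; scale forced to 1")
        std = np.where(degenerate, 1.0, std)
    return ScalerParams(mean, std)


def apply_scaler(ws: WindowSet, params: ScalerParams) -> WindowSet:
    scaled = (ws.windows - params.mean) / params.std
    return WindowSet(scaled, ws.labels.copy(), ws.starts.copy(),
                     ws.window_sz, ws.n_channels, ws.sampling_rate_hz)


def preprocess_participant(
    lrec: LabeledRecording,
    cfg: RunConfig,
    mapping: dict | None = None,
    trim: bool | None = None,
) -> WindowSet:
    """Harmonize -> (optionally) trim -> window -> static filter -> scale, for
    one participant. ``mapping`` defaults to identity for already-harmonized
    labels."""
    if mapping is not None:
        lrec = harmonize_labels(lrec, mapping)
    if trim is None:
        trim = cfg.apply_edge_trim
    if trim:
        lrec = trim_activity_edges(lrec, cfg.edge_trim_samples)
    ws = segment_windows(lrec, cfg)
    ws = filter_static_windows(ws, cfg.static_rms_limit_mps2)
    scaler = fit_participant_scaler(lrec)
    return apply_scaler(ws, scaler)
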