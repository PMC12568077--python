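"""Window predictions -> per-sample mask -> walking bouts -> strides.

Stride events follow the shank-gyro convention: mid-swing is a prominent
mediolateral angular-velocity maximum; heel strike is the largest resultant
acceleration peak in the first half of each mid-swing-to-mid-swing interval;
a stride spans heel strike to next heel strike and is time-normalized to 101
points for ensemble averaging.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from .containers import BoutList, GaitMask, ImuRecording, PredictionSet, StrideSet


def predictions_to_mask(preds: PredictionSet, n_samples: int,
                        sampling_rate_hz: float = 100.0) -> GaitMask:
    """Per-sample walking mask from overlapping window predictions.

    A sample is walking iff the proportion of covering windows predicted
    walking exceeds 0.5 (strict); samples covered by no window are False.
    """
    votes = np.zeros(n_samples, dtype=int)
    coverage = np.zeros(n_samples, dtype=int)
    for start, label in zip(preds.starts, preds.predicted_labels):
        end = min(start + preds.window_sz, n_samples)
        if start >= n_samples or end <= 0:
            raise ValueError(f"window at {start} falls outside [0, {n_samples})")
        coverage[start:end] += 1
        if label == "walking":
            votes[start:end] += 1
    mask = (2 * votes) > coverage
    return GaitMask(mask, sampling_rate_hz, provenance="ml_model")


def mask_to_bouts(mask: GaitMask, min_duration_s: float = 0.0) -> BoutList:
    """Maximal true-runs as half-open intervals, dropping runs shorter than
    ``min_duration_s``."""
    m = mask.is_walking.astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], m, [0]])))
    min_len = min_duration_s * mask.sampling_rate_hz
    intervals = [
        (int(s), int(e))
        for s, e in zip(edges[::2], edges[1::2])
        if (e - s) >= min_len
    ]
    return BoutList(intervals, min_duration_s)


def bouts_to_mask(bouts: BoutList, n_samples: int,
                  sampling_rate_hz: float = 100.0) -> GaitMask:
    m = np.zeros(n_samples, dtype=bool)
    for s, e in bouts.intervals:
        m[s:e] = True
    return GaitMask(m, sampling_rate_hz, provenance="ml_model")


def detect_strides(
    rec: ImuRecording,
    bout: tuple,
    bout_id: int = 0,
    peak_height_dps: float = 50.0,
    min_separation_s: float = 0.5,
    duration_gate_s: tuple = (0.4, 4.0),
) -> StrideSet:
    """Detect mid-swing peaks, heel strikes, and normalized strides in a bout.

    Mid-swing peaks: local maxima of the mediolateral gyro with height >=
    ``peak_height_dps`` and separation >= ``min_separation_s``. For each
    successive peak pair (t_i, t_{i+1}), heel strike = argmax of the
    resultant acceleration over [t_i, t_i + (t_{i+1}-t_i)/2] (left endpoint
    included). Strides are consecutive heel-strike pairs with duration
    inside ``duration_gate_s``. Fewer than 2 mid-swing peaks -> empty set.
    """
    b0, b1 = bout
    if not (0 <= b0 < b1 <= rec.n_samples):
        raise ValueError(f"bout ({b0}, {b1}) outside recording")
    ml = rec.gyro[b0:b1, 1]
    rate = rec.rate
    peaks, _ = sp_signal.find_peaks(
        ml, height=peak_height_dps, distance=max(int(round(min_separation_s * rate)), 1)
    )
    if len(peaks) < 2:
        return StrideSet.empty()
    anorm = np.linalg.norm(rec.accel[b0:b1], axis=1)
    heel_strikes = []
    for p, q in zip(peaks[:-1], peaks[1:]):
        half_end = p + (q - p) // 2
        heel_strikes.append(p + int(np.argmax(anorm[p:half_end + 1])))
    heel_strikes = np.asarray(heel_strikes, dtype=int) + b0

    strides, bounds = [], []
    lo, hi = duration_gate_s
    for h0, h1 in zip(heel_strikes[:-1], heel_strikes[1:]):
        dur = (h1 - h0) / rate
        if not lo <= dur <= hi:
            continue
        strides.append(normalize_stride(rec, (h0, h1)))
        bounds.append((h0, h1))
    if not strides:
        return StrideSet(
            np.empty((0, 101)), np.empty((0, 2), dtype=int), heel_strikes,
            np.array([], dtype=int), peaks + b0,
        )
    return StrideSet(
        np.stack(strides),
        np.array(bounds, dtype=int),
        heel_strikes,
        np.full(len(strides), bout_id, dtype=int),
        peaks + b0,
    )


def extract_strides(rec: ImuRecording, bouts: BoutList, **kw) -> StrideSet:
    """Run :func:`detect_strides` over every bout and concatenate."""
    return StrideSet.concatenate(
        [detect_strides(rec, iv, bout_id=i, **kw) for i, iv in enumerate(bouts.intervals)]
    )


def normalize_stride(rec: ImuRecording, hs_pair: tuple) -> np.ndarray:
    """Mediolateral angular velocity from heel strike to next heel strike
    (inclusive), linearly interpolated onto 101 equally spaced points."""
    h0, h1 = hs_pair
    if h1 - h0 < 1:
        raise ValueError("stride must span at least 2 samples")
    seg = rec.gyro[h0:h1 + 1, 1]
    grid = np.linspace(0, len(seg) - 1, 101)
    return np.interp(grid, np.arange(len(seg)), seg)


def ensemble_average(strides: StrideSet):
    """Pointwise mean and standard deviation of the normalized strides."""
    if strides.n_strides == 0:
        raise ValueError("cannot ensemble-average an empty StrideSet")
    return strides.strides.mean(axis=0), strides.strides.std(axis=0)
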