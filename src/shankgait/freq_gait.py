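"""Heuristic frequency-harmonic gait detector.

A 10 s sliding window of a single shank signal (default: mediolateral
angular velocity) is first checked for activity (RMS > 50 deg/s). Active
windows are detrended, Hann-tapered, and transformed to a one-sided
amplitude spectrum in physical units; the fundamental is the most prominent
spectral peak inside the locomotor band, and the window is classified as
gait when at least ``min_peaks`` of the first ``n_harmonics`` integer
multiples of the fundamental carry a spectral peak of prominence >=
``peak_prominence``. Window decisions are aggregated to a per-sample
Boolean mask by strict-majority coverage, mirroring the ML-side rule so the
two methods are directly comparable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal
from scipy.fft import rfft, rfftfreq

from .config import FreqDetectorConfig
from .containers import GaitMask, ImuRecording


def extract_signal(rec: ImuRecording, which: str) -> np.ndarray:
    """Pull the detector's scalar input signal from a shank-frame recording."""
    if which == "ml_gyro":
        return rec.gyro[:, 1]
    if which == "v_accel":
        return rec.accel[:, 2]
    if which == "accel_norm":
        return np.linalg.norm(rec.accel, axis=1)
    if which == "gyro_norm":
        return np.linalg.norm(rec.gyro, axis=1)
    raise ValueError(f"unknown detector signal {which!r}")


def is_active_window(segment: np.ndarray, cfg: FreqDetectorConfig) -> bool:
    """Active iff the RMS of the raw segment exceeds the rest threshold."""
    rms = float(np.sqrt(np.mean(np.square(segment, dtype=float))))
    return rms > cfg.rest_threshold_dps


def amplitude_spectrum(segment: np.ndarray, rate: float):
    """One-sided amplitude spectrum, scaled 2|X|/N, of the detrended,
    Hann-tapered segment.

    With the Hann taper's coherent gain of 1/2, an on-bin sinusoid of
    amplitude A reads ~A/2, so the prominence threshold of 5 corresponds to
    a ~10 deg/s sinusoidal component. This scaling keeps broadband-noise
    bins low enough that unstructured active motion rarely produces
    spurious harmonic peaks.
    """
    seg = sp_signal.detrend(np.asarray(segment, dtype=float), type="linear")
    win = np.hanning(len(seg))
    spec = np.abs(rfft(seg * win)) * 2.0 / len(seg)
    freqs = rfftfreq(len(seg), d=1.0 / rate)
    return freqs, spec


def _harmonic_count(freqs, spec, cfg) -> int:
    peaks, props = sp_signal.find_peaks(spec, prominence=cfg.peak_prominence)
    lo, hi = cfg.locomotor_band_hz
    in_band = (freqs[peaks] >= lo) & (freqs[peaks] <= hi)
    if not in_band.any():
        return 0
    band_peaks = peaks[in_band]
    band_prom = props["prominences"][in_band]
    f0 = float(freqs[band_peaks[np.argmax(band_prom)]])
    df = freqs[1] - freqs[0]
    peak_freqs = freqs[peaks]
    count = 0
    for k in range(1, cfg.n_harmonics + 1):
        target = k * f0
        tol = max(cfg.harmonic_tolerance * target, 1.5 * df)
        if np.any(np.abs(peak_freqs - target) <= tol):
            count += 1
    return count


def classify_window(segment: np.ndarray, cfg: FreqDetectorConfig,
                    rate: float) -> bool:
    """Gait iff >= ``min_peaks`` of the first ``n_harmonics`` harmonics of
    the in-band fundamental carry a prominent spectral peak."""
    freqs, spec = amplitude_spectrum(segment, rate)
    return _harmonic_count(freqs, spec, cfg) >= cfg.min_peaks


def detect_gait(rec: ImuRecording, cfg: FreqDetectorConfig | None = None) -> GaitMask:
    """Per-sample Boolean gait mask from sliding-window harmonic analysis.

    Windows of ``window_seconds`` at ``hop_seconds`` stride are classified
    (inactive windows are not-gait); a sample is gait iff more than half of
    the windows covering it were classified gait. Samples past the last
    window inherit the last window's class; a recording shorter than one
    window yields an all-false mask with a warning.
    """
    cfg = cfg or FreqDetectorConfig()
    sig = extract_signal(rec, cfg.signal)
    n = len(sig)
    rate = rec.rate
    win = int(round(cfg.window_seconds * rate))
    hop = int(round(cfg.hop_seconds * rate))
    if n < win:
        warnings.warn("recording shorter than one detector window; all-false mask")
        return GaitMask(np.zeros(n, dtype=bool), rate, provenance="freq")
    gait_votes = np.zeros(n, dtype=int)
    coverage = np.zeros(n, dtype=int)
    last_end, last_cls = 0, False
    for start in range(0, n - win + 1, hop):
        seg = sig[start:start + win]
        cls = is_active_window(seg, cfg) and classify_window(seg, cfg, rate)
        coverage[start:start + win] += 1
        if cls:
            gait_votes[start:start + win] += 1
        last_end, last_cls = start + win, cls
    mask = (2 * gait_votes) > coverage  # strict majority; zero coverage -> False
    if last_end < n:
        mask[last_end:] = last_cls
    return GaitMask(mask, rate, provenance="freq")
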