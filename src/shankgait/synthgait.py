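"""Synthetic shank-IMU generator with exact ground truth.

Walking is built as a truncated Fourier series of the stride frequency: the
mediolateral angular velocity is a sum of the first four harmonics with
phases aligned so each cycle has one dominant mid-swing peak; the resultant
acceleration carries gravity plus a decaying 15 Hz heel-strike transient
planted at a fixed phase offset after each mid-swing. Cycle times are
jittered by a coefficient of variation and Gaussian channel noise is added.
Gait-speed strata follow the slow (<0.8 m/s) / average (0.8-1.2 m/s) /
fast (>1.2 m/s) convention, with the slow stratum carrying weaker harmonic
content — the feature that degrades frequency-harmonic detection at slow
speeds. "Static" is gravity plus small noise; "other" is active,
non-periodic motion dominated by slow postural sway, so it exercises the
detector's active-but-not-gait path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .containers import (
    GaitMask,
    ImuRecording,
    LabeledRecording,
    RecordingMeta,
)

GRAVITY = 9.81


@dataclass
class GaitProfile:
    """Parameters of one synthetic walking condition.

    ``harmonic_amplitudes`` are fractions of the mid-swing amplitude assigned
    to harmonics 1..4 of the stride frequency (before normalization so the
    per-cycle peak equals ``midswing_amplitude_dps``).
    """

    gait_speed_mps: float = 1.0
    stride_frequency_hz: float = 0.9
    midswing_amplitude_dps: float = 300.0
    heelstrike_amplitude_mps2: float = 8.0
    harmonic_amplitudes: tuple = (1.0, 0.45, 0.25, 0.12)
    jitter: float = 0.03
    noise_sd_gyro_dps: float = 3.0
    noise_sd_accel_mps2: float = 0.3

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ValueError("harmonic amplitudes must be >= 0")
        if not 0.3 < self.stride_frequency_hz < 2.5:
            raise ValueError("stride_frequency_hz must lie in (0.3, 2.5)")

    @property
    def stratum(self) -> str:
        if self.gait_speed_mps < 0.8:
            return "slow"
        if self.gait_speed_mps <= 1.2:
            return "average"
        return "fast"

    def replace(self, **kw) -> "GaitProfile":
        return dataclasses.replace(self, **kw)


#: Speed -> cadence/amplitude lookup reproducing the qualitative
#: speed-dependent detectability (weak harmonics at very slow gait).
SLOW_PROFILE = GaitProfile(
    gait_speed_mps=0.3, stride_frequency_hz=0.45,
    midswing_amplitude_dps=120.0, heelstrike_amplitude_mps2=4.0,
    harmonic_amplitudes=(1.0, 0.22, 0.10, 0.05),
)
AVERAGE_PROFILE = GaitProfile()
FAST_PROFILE = GaitProfile(
    gait_speed_mps=1.4, stride_frequency_hz=1.05,
    midswing_amplitude_dps=360.0, heelstrike_amplitude_mps2=10.0,
    harmonic_amplitudes=(1.0, 0.50, 0.30, 0.15),
)

PROFILES = {"slow": SLOW_PROFILE, "average": AVERAGE_PROFILE, "fast": FAST_PROFILE}


def profile_for_speed(speed_mps: float) -> GaitProfile:
    """Interpolate cadence/amplitudes linearly between the stratum anchors."""
    anchors = sorted(PROFILES.values(), key=lambda p: p.gait_speed_mps)
    speeds = [p.gait_speed_mps for p in anchors]
    s = float(np.clip(speed_mps, speeds[0], speeds[-1]))

    def lerp(attr):
        vals = [getattr(p, attr) for p in anchors]
        if isinstance(vals[0], tuple):
            return tuple(
                float(np.interp(s, speeds, [v[k] for v in vals]))
                for k in range(len(vals[0]))
            )
        return float(np.interp(s, speeds, vals))

    return GaitProfile(
        gait_speed_mps=speed_mps,
        stride_frequency_hz=lerp("stride_frequency_hz"),
        midswing_amplitude_dps=lerp("midswing_amplitude_dps"),
        heelstrike_amplitude_mps2=lerp("heelstrike_amplitude_mps2"),
        harmonic_amplitudes=lerp("harmonic_amplitudes"),
    )


def _cycle_starts(profile: GaitProfile, duration_s: float, rng) -> np.ndarray:
    """Cumulative cycle boundary times covering [0, duration_s]."""
    period = 1.0 / profile.stride_frequency_hz
    times = [0.0]
    while times[-1] < duration_s:
        t = period * (1.0 + profile.jitter * rng.standard_normal()) if profile.jitter else period
        times.append(times[-1] + max(t, 0.25 * period))
    return np.array(times)


def synth_walking(
    profile: GaitProfile,
    duration_s: float,
    rate: float = 100.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "synth",
):
    """Generate a walking segment with planted event ground truth.

    Returns ``(LabeledRecording, truth)`` where ``truth`` holds
    ``midswing_indices`` and ``heelstrike_indices`` (sample indices of the
    planted per-cycle mid-swing peak and heel-strike transient).
    """
    if duration_s < 2.0 / profile.stride_frequency_hz:
        raise ValueError("walking duration must cover at least 2 gait cycles")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    bounds = _cycle_starts(profile, duration_s, rng)

    # per-sample cycle phase theta in [0, 1)
    cyc = np.searchsorted(bounds, t, side="right") - 1
    cyc = np.clip(cyc, 0, len(bounds) - 2)
    theta = (t - bounds[cyc]) / (bounds[cyc + 1] - bounds[cyc])

    h = np.asarray(profile.harmonic_amplitudes, dtype=float)
    amps = profile.midswing_amplitude_dps * h / h.sum()
    # phases aligned at theta = 0.5 -> one dominant mid-swing peak per cycle
    gy = np.zeros(n)
    for k, a in enumerate(amps, start=1):
        gy += a * np.cos(2 * np.pi * k * (theta - 0.5))

    # anteroposterior acceleration: aligned two-harmonic shape -> positive skew;
    # mediolateral uses the (orthogonal) third harmonic so the horizontal
    # principal direction stays anteroposterior
    ax = 1.5 * np.cos(2 * np.pi * (theta - 0.3)) + 0.8 * np.cos(4 * np.pi * (theta - 0.3))
    ay = 0.4 * np.sin(6 * np.pi * theta)
    az = np.full(n, GRAVITY) + 0.5 * np.cos(4 * np.pi * (theta - 0.55))

    midswing_t = bounds[:-1] + 0.5 * (bounds[1:] - bounds[:-1])
    hs_t = bounds[:-1] + 0.8 * (bounds[1:] - bounds[:-1])
    midswing_idx = np.round(midswing_t * rate).astype(int)
    hs_idx = np.round(hs_t * rate).astype(int)
    valid_ms = midswing_idx < n
    midswing_idx = midswing_idx[valid_ms]
    hs_idx = hs_idx[hs_idx < n - 1]

    # decaying 15 Hz heel-strike transient, maximum exactly at the planted sample
    for i in hs_idx:
        tail = min(n - i, int(round(0.15 * rate)))
        tt = np.arange(tail) / rate
        burst = profile.heelstrike_amplitude_mps2 * np.exp(-tt / 0.05) * np.cos(
            2 * np.pi * 15.0 * tt
        )
        az[i:i + tail] += burst
        ax[i:i + tail] += 0.4 * burst

    gx = 0.15 * gy + profile.noise_sd_gyro_dps * rng.standard_normal(n)
    gz = 0.10 * gy + profile.noise_sd_gyro_dps * rng.standard_normal(n)
    gy = gy + profile.noise_sd_gyro_dps * rng.standard_normal(n)
    accel = np.column_stack([ax, ay, az]) + profile.noise_sd_accel_mps2 * rng.standard_normal((n, 3))
    gyro = np.column_stack([gx, gy, gz])

    meta = RecordingMeta(subject_id, "proximal_shank", rate)
    rec = ImuRecording(t, accel, gyro, meta, frame="shank")
    labels = np.full(n, "walking", dtype=object)
    truth = {"midswing_indices": midswing_idx, "heelstrike_indices": hs_idx}
    return LabeledRecording(rec, labels), truth


def synth_static(
    duration_s: float,
    rate: float = 100.0,
    noise_sd: tuple = (0.05, 1.0),
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "synth",
) -> LabeledRecording:
    """Gravity plus small Gaussian noise (defaults 0.05 m/s^2, 1 deg/s)."""
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    accel = np.tile([0.0, 0.0, GRAVITY], (n, 1)) + noise_sd[0] * rng.standard_normal((n, 3))
    gyro = noise_sd[1] * rng.standard_normal((n, 3))
    meta = RecordingMeta(subject_id, "proximal_shank", rate)
    rec = ImuRecording(t, accel, gyro, meta, frame="shank")
    return LabeledRecording(rec, np.full(n, "static", dtype=object))


def synth_other(
    duration_s: float,
    rate: float = 100.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "synth",
    sway_rms_dps: float = 70.0,
    broadband_rms_dps: float = 12.0,
) -> LabeledRecording:
    """Active but non-gait motion (household-activity surrogate).

    Band-limited (0-8 Hz) non-periodic motion: a large slow postural-sway
    component (0.05-0.3 Hz) plus low-level broadband (<8 Hz) noise. The
    mediolateral gyro RMS exceeds the 50 deg/s rest threshold, but the
    spectrum has no stable harmonic structure in the locomotor band.
    """
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate

    def sway(rms):
        sos = sp_signal.butter(4, [0.05, 0.3], btype="band", fs=rate, output="sos")
        x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n + 2000))[1000:-1000]
        return x / max(np.sqrt(np.mean(x**2)), 1e-12) * rms

    def broadband(rms):
        sos = sp_signal.butter(4, 8.0, btype="low", fs=rate, output="sos")
        x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
        return x / max(np.sqrt(np.mean(x**2)), 1e-12) * rms

    gyro = np.column_stack(
        [sway(0.6 * sway_rms_dps) + broadband(broadband_rms_dps),
         sway(sway_rms_dps) + broadband(broadband_rms_dps),
         sway(0.4 * sway_rms_dps) + broadband(broadband_rms_dps)]
    )
    accel = np.tile([0.0, 0.0, GRAVITY], (n, 1)) + np.column_stack(
        [sway(1.2) + broadband(0.6) for _ in range(3)]
    )
    meta = RecordingMeta(subject_id, "proximal_shank", rate)
    rec = ImuRecording(t, accel, gyro, meta, frame="shank")
    return LabeledRecording(rec, np.full(n, "other", dtype=object))


#: Default activity schedule: emulates the clinical labeled-session mix
#: (quiet standing + self-selected walking, ~48% / 52% of labeled time).
DEFAULT_SCHEDULE = (("static", 96.0), ("walking", 105.0))

#: Schedule used for 3-class classifier training cohorts.
TRAINING_SCHEDULE = (("static", 40.0), ("walking", 60.0), ("other", 40.0))


def schedule_mixture(schedule=DEFAULT_SCHEDULE) -> dict:
    """Fraction of scheduled time per activity label."""
    total = sum(d for _, d in schedule)
    out: dict = {}
    for label, d in schedule:
        out[label] = out.get(label, 0.0) + d / total
    return out


def _concat_segments(segments, subject_id, rate) -> LabeledRecording:
    accel = np.concatenate([s.recording.accel for s in segments])
    gyro = np.concatenate([s.recording.gyro for s in segments])
    labels = np.concatenate([s.labels for s in segments])
    n = len(labels)
    t = np.arange(n) / rate
    meta = RecordingMeta(subject_id, "proximal_shank", rate)
    rec = ImuRecording(t, accel, gyro, meta, frame="shank")
    return LabeledRecording(rec, labels)


def synth_subject(
    subject_id: str,
    seed: int | np.random.SeedSequence,
    schedule=DEFAULT_SCHEDULE,
    base_profile: GaitProfile | None = None,
    rate: float = 100.0,
):
    """One subject's recording from an activity schedule, with ground truth.

    Subject-level perturbations: harmonic amplitudes +/-20%, stride frequency
    +/-10%, drawn once from the subject seed. Returns
    ``(LabeledRecording, truth)`` with truth carrying the walking mask and
    planted event indices (offset to recording coordinates).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    profile = base_profile or AVERAGE_PROFILE
    profile = profile.replace(
        midswing_amplitude_dps=profile.midswing_amplitude_dps * rng.uniform(0.8, 1.2),
        heelstrike_amplitude_mps2=profile.heelstrike_amplitude_mps2 * rng.uniform(0.8, 1.2),
        stride_frequency_hz=profile.stride_frequency_hz * rng.uniform(0.9, 1.1),
    )
    seg_seeds = ss.spawn(len(schedule))
    segments = []
    midswing, heelstrike = [], []
    offset = 0
    for (label, dur), seg_seed in zip(schedule, seg_seeds):
        if label == "walking":
            seg, truth = synth_walking(profile, dur, rate, seg_seed, subject_id)
            midswing.append(truth["midswing_indices"] + offset)
            heelstrike.append(truth["heelstrike_indices"] + offset)
        elif label == "static":
            seg = synth_static(dur, rate, seed=seg_seed, subject_id=subject_id)
        elif label == "other":
            seg = synth_other(dur, rate, seed=seg_seed, subject_id=subject_id)
        else:
            raise ValueError(f"unknown schedule label {label!r}")
        segments.append(seg)
        offset += seg.n_samples
    lrec = _concat_segments(segments, subject_id, rate)
    mask = GaitMask(lrec.labels == "walking", rate, provenance="truth")
    truth = {
        "mask": mask,
        "midswing_indices": np.concatenate(midswing) if midswing else np.array([], dtype=int),
        "heelstrike_indices": np.concatenate(heelstrike) if heelstrike else np.array([], dtype=int),
        "profile": profile,
    }
    return lrec, truth


def synth_cohort(
    n_subjects: int,
    seed: int = 0,
    schedule=DEFAULT_SCHEDULE,
    strata: tuple = ("slow", "average", "fast"),
    rate: float = 100.0,
):
    """Generate ``n_subjects`` recordings with subject-disjoint seeds.

    Subjects cycle round-robin through the gait-speed ``strata``. Returns a
    list of ``(LabeledRecording, truth)`` pairs; regeneration with the same
    master seed reproduces the cohort exactly.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_subjects)
    cohort = []
    for i, sseed in enumerate(subject_seeds):
        stratum = strata[i % len(strata)]
        cohort.append(
            synth_subject(f"S{i:03d}", sseed, schedule, PROFILES[stratum], rate)
        )
    return cohort
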