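import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from shankgait import preprocess, synthgait
from shankgait.config import RunConfig
from shankgait.containers import LabeledRecording

from conftest import make_labeled, make_recording


def _calibration_fixture(rotation=None, seed=3):
    """Standing (3 s) + walking (60 s) in the shank frame, optionally
    de-rotated by a known rotation to emulate an arbitrary mount."""
    walk, _ = synthgait.synth_walking(synthgait.AVERAGE_PROFILE, 60.0, seed=seed)
    stand = synthgait.synth_static(3.0, seed=seed + 1)
    accel = np.vstack([stand.recording.accel, walk.recording.accel])
    gyro = np.vstack([stand.recording.gyro, walk.recording.gyro])
    if rotation is not None:
        accel = rotation.apply(accel)
        gyro = rotation.apply(gyro)
    rec = make_recording(accel, gyro, frame="raw")
    return rec, (0, 300), (300, 6300)


class TestCalibration:
    def test_gravity_along_x_maps_to_vertical(self):
        # sensor mounted so gravity reads along +x: rotation y->x? use the
        # rotation sending z to x, then calibration must undo it.
        rot = Rotation.from_rotvec([0, np.pi / 2, 0])  # z -> x
        rec, standing, walking = _calibration_fixture(rotation=rot)
        assert abs(np.mean(rec.accel[0:300, 0]) - 9.81) < 0.1  # gravity on +x
        cal = preprocess.calibrate_to_shank_frame(rec, standing, walking)
        mean_stand = cal.accel[0:300].mean(axis=0)
        norm = np.linalg.norm(mean_stand)
        np.testing.assert_allclose(mean_stand, [0, 0, norm], atol=1e-9 * norm + 0.02)
        assert cal.frame == "shank"

    def test_identity_fixed_point(self):
        rec, standing, walking = _calibration_fixture(rotation=None)
        rot = preprocess.compute_calibration(rec, standing, walking)
        assert rot.magnitude() < np.deg2rad(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigidity_norms_and_orthonormality(self, seed):
        rng = np.random.default_rng(seed)
        rot = Rotation.from_rotvec(rng.normal(size=3))
        rec, standing, walking = _calibration_fixture(rotation=rot, seed=seed + 10)
        r = preprocess.compute_calibration(rec, standing, walking)
        m = r.as_matrix()
        np.testing.assert_allclose(m.T @ m, np.eye(3), atol=1e-12)
        cal = preprocess.calibrate_to_shank_frame(rec, standing, walking)
        np.testing.assert_allclose(
            np.linalg.norm(cal.accel, axis=1),
            np.linalg.norm(rec.accel, axis=1), atol=1e-9,
        )

    def test_not_quiet_standing_rejected(self):
        rec, standing, walking = _calibration_fixture()
        accel = rec.accel.copy()
        accel[0:300, 2] += 5 * np.sin(np.arange(300))  # jostled "standing"
        noisy = make_recording(accel, rec.gyro)
        with pytest.raises(preprocess.CalibrationError, match="not quiet"):
            preprocess.calibrate_to_shank_frame(noisy, standing, walking)


class TestDownsample:
    def _hf_recording(self, freq_hz, n=16000, rate=1600.0):
        t = np.arange(n) / rate
        a = np.column_stack([np.sin(2 * np.pi * freq_hz * t),
                             np.zeros(n), np.full(n, 9.81)])
        return make_recording(a, np.zeros((n, 3)), rate=rate)

    def test_length_arithmetic(self):
        rec = self._hf_recording(1.0)
        out = preprocess.downsample(rec, 100.0)
        assert out.n_samples == 1000
        assert out.rate == 100.0

    def test_passband_amplitude_preserved(self):
        rec = self._hf_recording(1.0)
        out = preprocess.downsample(rec, 100.0)
        # compare against the analytic 1 Hz sinusoid on the decimated grid
        t = np.arange(out.n_samples) / 100.0
        ref = np.sin(2 * np.pi * 1.0 * t)
        core = slice(100, 900)  # ignore filter edge effects
        amp = np.ptp(out.accel[core, 0]) / np.ptp(ref[core])
        assert abs(amp - 1.0) < 0.01

    def test_alias_suppressed(self):
        rec = self._hf_recording(700.0)
        out = preprocess.downsample(rec, 100.0)
        power_in = np.mean(rec.accel[:, 0] ** 2)
        power_out = np.mean(out.accel[100:900, 0] ** 2)
        assert power_out < 0.01 * power_in

    def test_non_integer_factor(self):
        rec = self._hf_recording(1.0, n=1500, rate=150.0)
        with pytest.raises(ValueError, match="integer multiple"):
            preprocess.downsample(rec, 100.0)


class TestHarmonizeLabels:
    MAP = {"lying": "static", "sitting": "static", "standing": "static",
           "vacuuming": "other", "rope_jumping": "drop", "walk": "walking"}

    def test_static_family(self):
        lrec = make_labeled(["lying", "sitting", "standing"])
        out = preprocess.harmonize_labels(lrec, self.MAP)
        assert (out.labels == "static").all()
        assert out.retained.all()

    def test_other_and_drop(self):
        lrec = make_labeled(["vacuuming", "rope_jumping"])
        out = preprocess.harmonize_labels(lrec, self.MAP)
        assert out.labels[0] == "other" and out.retained[0]
        assert out.labels[1] == "unlabeled" and not out.retained[1]

    def test_unmapped_label_named(self):
        lrec = make_labeled(["surfing"])
        with pytest.raises(KeyError, match="surfing"):
            preprocess.harmonize_labels(lrec, self.MAP)


class TestTrimActivityEdges:
    def test_single_run(self):
        lrec = make_labeled(["walking"] * 1500)
        out = preprocess.trim_activity_edges(lrec, 500)
        assert out.retained.sum() == 500
        assert out.retained[500:1000].all()
        assert not out.retained[:500].any() and not out.retained[1000:].any()

    def test_short_run_removed_entirely(self):
        lrec = make_labeled(["walking"] * 900)
        out = preprocess.trim_activity_edges(lrec, 500)
        assert not out.retained.any()

    def test_two_runs_boundaries(self):
        lrec = make_labeled(["walking"] * 2000 + ["static"] * 2000)
        out = preprocess.trim_activity_edges(lrec, 500)
        # brute-force expectation: each run keeps its middle 1000 samples
        expected = np.zeros(4000, dtype=bool)
        expected[500:1500] = True
        expected[2500:3500] = True
        np.testing.assert_array_equal(out.retained, expected)


def brute_force_window_count(run_lengths, window_sz, hop):
    """Enumerate admissible window starts run by run."""
    total = 0
    for n in run_lengths:
        starts = [s for s in range(0, n, hop) if s + window_sz <= n]
        total += len(starts)
    return total


class TestSegmentWindows:
    def _cfg(self, window_seconds, overlap=0.5):
        return RunConfig(window_seconds=window_seconds, overlap_fraction=overlap)

    def test_three_windows(self):
        lrec = make_labeled(["walking"] * 1000)
        ws = preprocess.segment_windows(lrec, self._cfg(5.0))
        assert ws.n_windows == 3
        np.testing.assert_array_equal(ws.starts, [0, 250, 500])
        assert (ws.labels == "walking").all()

    def test_run_shorter_than_window(self):
        lrec = make_labeled(["walking"] * 499)
        assert preprocess.segment_windows(lrec, self._cfg(5.0)).n_windows == 0

    def test_windows_never_span_boundaries(self):
        labels = ["walking"] * 700 + ["static"] * 700
        lrec = make_labeled(labels)
        ws = preprocess.segment_windows(lrec, self._cfg(5.0))
        for s, l in zip(ws.starts, ws.labels):
            assert len(set(labels[s:s + 500])) == 1
            assert labels[s] == l

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 900), min_size=1, max_size=6),
           st.integers(0, 2))
    def test_count_matches_enumeration_oracle(self, run_lengths, which_overlap):
        overlap = [0.0, 0.5, 0.75][which_overlap]
        cfg = self._cfg(1.0, overlap)  # window 100 samples at 100 Hz
        labels = []
        for i, n in enumerate(run_lengths):
            labels += ["walking" if i % 2 == 0 else "static"] * n
        lrec = make_labeled(labels)
        ws = preprocess.segment_windows(lrec, cfg)
        assert ws.n_windows == brute_force_window_count(
            run_lengths, cfg.window_sz, cfg.hop)


class TestStaticFilter:
    def _window_set(self, az, label="static"):
        n = len(az)
        lrec = make_labeled([label] * n,
                            accel=np.column_stack([np.zeros(n), np.zeros(n), az]))
        return preprocess.segment_windows(lrec, RunConfig(window_seconds=n / 100))

    def test_constant_gravity_kept(self):
        ws = self._window_set(np.full(500, 9.81))
        assert preprocess.filter_static_windows(ws).n_windows == 1

    def test_jostled_static_removed(self):
        t = np.arange(500) / 100
        az = 9.81 + 2 * np.sqrt(2) * np.sin(2 * np.pi * 2 * t)  # RMS 2 exactly
        ws = self._window_set(az)
        assert preprocess.static_window_rms(ws.windows[0]) == pytest.approx(2.0, abs=1e-9)
        assert preprocess.filter_static_windows(ws).n_windows == 0

    def test_boundary_exactly_one_removed(self):
        # alternating +/-1 about a constant: deviation RMS exactly 1.0 in
        # floating point; strict "less than 1" must remove it
        az = 10.0 + np.where(np.arange(500) % 2 == 0, 1.0, -1.0)
        ws = self._window_set(az)
        assert preprocess.static_window_rms(ws.windows[0]) == 1.0
        assert preprocess.filter_static_windows(ws, limit=1.0).n_windows == 0

    def test_non_static_untouched(self):
        t = np.arange(500) / 100
        az = 9.81 + 5 * np.sin(2 * np.pi * 2 * t)
        ws = self._window_set(az, label="walking")
        assert preprocess.filter_static_windows(ws).n_windows == 1


class TestParticipantScaler:
    def test_walking_samples_standardized(self, walking_60s):
        lrec, _ = walking_60s
        params = preprocess.fit_participant_scaler(lrec)
        ws = preprocess.segment_windows(lrec, RunConfig())
        scaled = preprocess.apply_scaler(ws, params)
        flat = scaled.windows.reshape(-1, 6)
        assert np.all(np.abs(flat.mean(axis=0)) < 1e-2)
        assert np.all(np.abs(flat.std(axis=0) - 1) < 0.1)

    def test_exact_on_full_walking_signal(self, walking_60s):
        lrec, _ = walking_60s
        params = preprocess.fit_participant_scaler(lrec)
        chans = lrec.recording.channels()
        z = (chans - params.mean) / params.std
        assert np.all(np.abs(z.mean(axis=0)) < 1e-6)
        assert np.all(np.abs(z.std(axis=0) - 1) < 1e-6)

    def test_constant_channel_guard(self):
        n = 1000
        accel = np.tile([0.0, 0.0, 9.81], (n, 1))
        gyro = np.column_stack([np.sin(np.arange(n) / 10),
                                np.zeros(n), np.zeros(n)])
        lrec = make_labeled(["walking"] * n, accel=accel, gyro=gyro)
        with pytest.warns(UserWarning, match="degenerate"):
            params = preprocess.fit_participant_scaler(lrec)
        assert np.all(params.std[np.abs(params.std - 1) < 1e-12] == 1.0)

    def test_no_walking_error(self):
        lrec = make_labeled(["static"] * 100)
        with pytest.raises(ValueError, match="walking"):
            preprocess.fit_participant_scaler(lrec)

    def test_participants_scaled_independently(self):
        a, _ = synthgait.synth_walking(synthgait.AVERAGE_PROFILE, 30, seed=1)
        gain = a.replace(recording=make_recording(
            a.recording.accel * 2.0, a.recording.gyro * 2.0))
        pa = preprocess.fit_participant_scaler(a)
        pb = preprocess.fit_participant_scaler(gain)
        np.testing.assert_allclose(pb.std, 2 * pa.std, rtol=1e-9)


def test_pipeline_deterministic(cfg):
    lrec, _ = synthgait.synth_subject("S0", 5, synthgait.TRAINING_SCHEDULE)
    a = preprocess.preprocess_participant(lrec, cfg, trim=False)
    b = preprocess.preprocess_participant(lrec, cfg, trim=False)
    np.testing.assert_array_equal(a.windows, b.windows)
    assert (a.labels == b.labels).all()


def test_no_window_contains_removed_samples(cfg):
    lrec, _ = synthgait.synth_subject("S0", 6, synthgait.TRAINING_SCHEDULE)
    trimmed = preprocess.trim_activity_edges(lrec, 100)
    ws = preprocess.segment_windows(trimmed, cfg)
    for s in ws.starts:
        assert trimmed.retained[s:s + ws.window_sz].all()
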