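# Methods

## Signals, frames and conventions

Recordings are tri-axial accelerometer (m/s²) and gyroscope (deg/s) series
at 100 Hz; higher-rate sources are anti-alias filtered (8th-order
Butterworth, zero-phase, cutoff 0.4 × target rate) and decimated by the
integer factor. In the shank frame x is anteroposterior, y mediolateral,
z vertical (gravity along +z). Sample indices are 0-based and all
intervals are half-open `[start, end)`.

Calibration is a two-step rigid rotation: the mean quiet-standing
acceleration is rotated onto +z, then a rotation about the vertical aligns
the first horizontal principal direction of a walking section with +x. The
sign of +x is fixed by requiring positive skewness of the anteroposterior
walking acceleration (forward progression produces asymmetric braking/
propulsive peaks); ties break toward +x. A standing interval whose
acceleration-norm RMS deviation exceeds 1 m/s² is rejected as not quiet.

## Preprocessing

Labels are harmonized onto seven classes (static, walking, running,
cycling, stair ascent, stair descent, other); dropped or unlabeled samples
are kept in place but marked non-retained, which is equivalent to splitting
the recording — windowing never crosses a non-retained sample. For
PAMAP2-style protocol data, 500 samples are trimmed from both ends of every
contiguous activity run (runs ≤ 1000 samples vanish); trimming is a
per-dataset flag because continuous lab/clinic recordings have no
transition contamination at activity boundaries. Wireless-dropout NaN gaps
≤ 0.2 s are linearly interpolated; longer gaps are marked non-retained.
PAMAP2 gyroscopes are converted from rad/s to deg/s, and the ±16 g
accelerometer channels are used (the ±6 g channels saturate at impacts).

Windows are 5 s (500 samples) with 50% overlap, cut per contiguous
single-label run; each window inherits its run's label. Static windows
must have an RMS acceleration *deviation* below 1 m/s², where the deviation
is the acceleration norm minus the window's own mean norm (a raw RMS of a
gravity-bearing signal could never be below 1 m/s², so the deviation
reading is the only self-consistent interpretation; the window mean is the
local gravity estimate). The gate is strict: RMS exactly at the limit is
removed. Per-participant channel standardization is fitted on that
participant's walking samples only and applied to all their windows;
channels with standard deviation < 1e−8 keep scale 1.

## Activity classifier

The network is built from scratch in numpy (conv2d with TensorFlow-style
"same" padding, batch normalization, inverted dropout, LSTM, dense), with
hand-derived backpropagation verified against central-difference numerical
gradients in the test suite. Layer graph for the default configuration
(window 500 × 6 channels): conv(32, 2×2, stride 2) → BN → ReLU →
conv(32, 2×2, stride 1) → BN, plus a conv(32, 2×2, stride 2) shortcut from
the input; add → ReLU → dropout 0.5 → flatten → reshape to a sequence of
250 steps × 96 features → BiLSTM (64 units per direction, concatenated
final states) → dropout 0.5 → dense → softmax (87,911 parameters).

Two choices here were genuinely open. The flatten-then-recurrent step is
underdetermined: we reshape so the temporal axis (250 steps) survives,
since a BiLSTM over an order-destroyed flat vector could not model temporal
structure. The BiLSTM width (64/direction) and the Adam learning rate
(1e−3) are configurable defaults. "Same" padding keeps the residual add
shape-consistent; gate order is i, f, g, o with forget bias 1; one integer
seed fans out (via seed sequences) to weight initialization, shuffling and
dropout, making retraining bit-reproducible in a single-threaded run.

Training uses sparse categorical cross-entropy, Adam, batch 64, early
stopping on validation loss with patience 10 (best-epoch weights restored).
Window probabilities convert to a per-sample mask by strict-majority
coverage voting (> 0.5 of covering windows; uncovered samples are false).

## Frequency-harmonic detector

Windows of 10 s slide at a 5 s hop over the mediolateral angular velocity
(vertical acceleration and the two vector norms are selectable). A window
is active when its raw RMS exceeds 50 deg/s. Active windows are linearly
detrended, Hann-tapered, and transformed to a one-sided amplitude spectrum
scaled 2|X|/N; under the Hann taper a sinusoid of amplitude A reads ≈ A/2,
so the prominence threshold 5 corresponds to a ~10 deg/s component. This
scaling (rather than compensating the taper's coherent gain) keeps
broadband-noise bins low: unstructured active motion then rarely shows
spurious prominent peaks, which matches the detector's intended selectivity.

The fundamental f₀ is the most prominent spectral peak within the
locomotor band (0.4–3.0 Hz; the floor admits the ~0.45 Hz stride frequency
of very slow, 0.3 m/s gait). Harmonic k ∈ {1..4} is present when a peak of
prominence ≥ 5 lies within k·f₀ ± max(0.15·k·f₀, 1.5·Δf) — the tolerance
grows with k to track leakage, and the 1.5-bin floor keeps the window
meaningful at low cadence where 15% of f₀ is below the 0.1 Hz resolution.
Gait requires ≥ 2 of the 4 harmonics; an active window with no in-band
peak is not-gait. Per-sample aggregation mirrors the classifier's
strict-majority rule (a tie at exactly half is not-gait), so the two masks
are directly comparable; samples after the last full window inherit its
class, and a recording shorter than one window yields an all-false mask
with a warning.

## Bouts and strides

Maximal true-runs of a mask form bouts; a minimum-duration filter is
available (default 0 s). Within a bout, mid-swing events are mediolateral
gyro maxima with height ≥ 50 deg/s and separation ≥ 0.5 s (the height
reuses the detector's rest threshold; the separation bounds cadence at
2 strides/s — both configurable). Heel strike is the argmax of the
resultant acceleration over the first half of each mid-swing-to-mid-swing
interval, left endpoint included. Strides are consecutive heel-strike
pairs gated to 0.4–4.0 s (wide enough for 0.3 m/s gait, excluding
event-detection artifacts), linearly interpolated onto 101 points with
endpoints preserved exactly. Ensemble averages report the pointwise mean
and population standard deviation.

## Synthetic data generator

The generator is template-based rather than a biomechanical simulation: it
exists to exercise every detector code path with exact ground truth.
Walking mediolateral angular velocity is a truncated Fourier series of the
stride frequency — four harmonics with phases aligned at mid-cycle, so each
cycle has a single dominant mid-swing peak whose height equals the profile
amplitude. Cycle durations are jittered (CV 3% by default), and Gaussian
noise (3 deg/s, 0.3 m/s²) is added per channel. The resultant acceleration
carries gravity plus a decaying 15 Hz heel-strike transient planted at 80%
of each cycle (within the first half of the following mid-swing interval),
whose maximum falls exactly on the planted sample — the ground truth used
by the stride tests. The anteroposterior acceleration is an asymmetric
two-harmonic shape (positive skew, for the calibration convention); the
mediolateral acceleration uses the orthogonal third harmonic so the
horizontal principal direction stays anteroposterior.

Speed strata anchor a lookup: slow = 0.3 m/s, f₀ 0.45 Hz, mid-swing
120 deg/s, harmonic fractions (1, 0.22, 0.10, 0.05); average = 1.0 m/s,
0.9 Hz, 300 deg/s, (1, 0.45, 0.25, 0.12); fast = 1.4 m/s, 1.05 Hz,
360 deg/s, (1, 0.50, 0.30, 0.15). The slow stratum is deliberately
*active* (RMS ≈ 60 deg/s > 50) but harmonically weak — that combination is
what makes frequency-based detection degrade at slow speeds while leaving
amplitude-threshold activity detection intact, the qualitative failure
mode the speed comparison reproduces. None of these values is claimed
physiological; amplitudes sit in the plausible shank range and all are
configurable.

"Static" is gravity plus small noise (0.05 m/s², 1 deg/s). "Other" is
active non-gait motion: band-limited (0–8 Hz) non-periodic motion dominated
by slow postural sway (0.05–0.3 Hz, ~70 deg/s RMS on the mediolateral
gyro) plus low-level broadband noise — active by RMS yet without stable
harmonic structure in the locomotor band, exercising the
active-but-not-gait path.

Cohorts draw per-subject perturbations (amplitudes ±20%, stride frequency
±10%) from a seed-sequence hierarchy (master → subject → segment), cycling
subjects through the three strata. The default schedule (96 s static +
105 s walking) emulates the labeled clinic sessions' ~48%/52% class mix; a
three-class schedule (static/walking/other) is provided for classifier
training. Ground-truth masks, mid-swing and heel-strike indices are
returned alongside every recording.

What the generator does **not** emulate: sensor drift and saturation,
turning, double-support asymmetries, inter-cycle waveform variability
beyond timing jitter, magnetometer effects, and the diversity of real
activities of daily living. Passing tests therefore demonstrate
correctness of the pipeline's mechanics and its qualitative speed-
robustness behavior, not clinical-grade performance on real recordings.

## Evaluation

Confusion matrices come from scikit-learn; accuracy, precision, recall and
F1 are computed one-vs-rest from the counts, with zero-denominator ratios
reported as NaN with a warning. Wilson score intervals use statsmodels,
with the k = 0 and k = n bounds pinned to exactly 0 and 1 (the closed form
is exact there; the library returns values a few ulp inside). Rounding
happens only at presentation. Multi-participant test summaries aggregate
by the median across participants; per-participant reports are retained.

## Problem sizes and numerics

The test suite and the acceptance script run the classifier smoke on a
12-subject cohort (10 train / 1 validation / 1 test, subject-disjoint,
~53 windows per subject from a 140 s three-class schedule), trained for up
to 6 epochs with patience 3 — the synthetic classes separate within 2–3
epochs, so longer schedules add nothing to the check. Detector suites use
60 s segments per cadence and 100 ten-second draws for the false-positive
rate. The network computes in float32 (float64 for gradient checking);
batch-norm uses momentum 0.9 and eps 1e−5; Adam uses the standard
bias-corrected moments with eps 1e−7.

## Known limitations

* The classifier is trained and validated here only on synthetic data; no
  claim transfers to real cohorts without retraining.
* The frequency detector's spectrum normalization and harmonic-search
  details are one concrete realization of a method family; all of its
  constants are configurable.
* Orientation handling is limited to the static+walking two-step
  alignment; there is no sensor-fusion filtering.
* Heel-strike identification assumes the largest resultant-acceleration
  peak in the first half-interval is the strike; pathologies that displace
  the impact peak will bias event times.
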