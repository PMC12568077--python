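"""Run configuration: windowing, static filter, detector, model and training.

Defaults reproduce the published pipeline configuration: 5 s windows with 50%
overlap at 100 Hz, a 1 m/s^2 RMS gate on static windows, a 10 s
frequency-detector window on mediolateral angular velocity with peak
prominence 5 and a 50 deg/s rest threshold, 2-of-4 harmonics, and the
ResNet+BiLSTM trained with Adam on sparse categorical cross-entropy at batch
size 64 with early-stopping patience 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

#: Default mapping of PAMAP2 protocol activity IDs onto the 7-class taxonomy.
#: ID 0 (transient) and 24 (rope jumping) are dropped; Nordic walking (7),
#: vacuuming (16) and ironing (17) fall into "other" (gait-like or ADL
#: activity that is not true level walking). Configurable per run.
DEFAULT_PAMAP2_LABEL_MAP = {
    0: "drop",
    1: "static",   # lying
    2: "static",   # sitting
    3: "static",   # standing
    4: "walking",
    5: "running",
    6: "cycling",
    7: "other",    # Nordic walking
    12: "stair_ascent",
    13: "stair_descent",
    16: "other",   # vacuum cleaning
    17: "other",   # ironing
    24: "drop",    # rope jumping
}


@dataclass
class FreqDetectorConfig:
    """Frequency-harmonic gait detector parameters.

    ``peak_prominence`` is in one-sided amplitude-spectrum units (deg/s for
    the default mediolateral gyro signal). ``locomotor_band_hz`` bounds the
    fundamental (cadence) search; the floor of 0.4 Hz keeps the very slow
    (0.3 m/s) stride frequency of ~0.45 Hz inside the band.
    """

    window_seconds: float = 10.0
    hop_seconds: float = 5.0
    rest_threshold_dps: float = 50.0
    n_harmonics: int = 4
    min_peaks: int = 2
    peak_prominence: float = 5.0
    locomotor_band_hz: tuple = (0.4, 3.0)
    harmonic_tolerance: float = 0.15
    signal: str = "ml_gyro"

    def __post_init__(self) -> None:
        if self.min_peaks > self.n_harmonics:
            raise ValueError("min_peaks must be <= n_harmonics")
        lo, hi = self.locomotor_band_hz
        if not lo < hi:
            raise ValueError("locomotor band low must be < high")
        if self.signal not in ("ml_gyro", "v_accel", "accel_norm", "gyro_norm"):
            raise ValueError(f"unknown detector signal {self.signal!r}")
        self.locomotor_band_hz = (float(lo), float(hi))


@dataclass
class ModelConfig:
    """ResNet+BiLSTM architecture parameters."""

    window_sz: int = 500
    n_channels: int = 6
    n_classes: int = 7
    conv_filters: int = 32
    conv_kernel: tuple = (2, 2)
    conv1_stride: int = 2
    conv2_stride: int = 1
    shortcut_stride: int = 2
    dropout_rate: float = 0.5
    bilstm_units_per_direction: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.conv1_stride, self.conv2_stride, self.shortcut_stride) < 1:
            raise ValueError("strides must be >= 1")
        if self.conv1_stride != self.shortcut_stride:
            raise ValueError(
                "conv1_stride must equal shortcut_stride so the residual add "
                "sees equal shapes"
            )
        self.conv_kernel = tuple(int(k) for k in self.conv_kernel)


@dataclass
class TrainingConfig:
    """Optimization protocol: Adam on sparse categorical cross-entropy."""

    batch_size: int = 64
    max_epochs: int = 80
    early_stopping_patience: int = 10
    optimizer: str = "adam"
    loss: str = "sparse_categorical_crossentropy"
    learning_rate: float = 1e-3
    monitor: str = "val_loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stopping_patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "sparse_categorical_crossentropy":
            raise ValueError("only sparse categorical cross-entropy is supported")
        if self.monitor != "val_loss":
            raise ValueError("early stopping monitors validation loss")


@dataclass
class RunConfig:
    """Top-level pipeline configuration; YAML round-trips losslessly."""

    window_seconds: float = 5.0
    overlap_fraction: float = 0.5
    target_rate_hz: float = 100.0
    static_rms_limit_mps2: float = 1.0
    edge_trim_samples: int = 500
    apply_edge_trim: bool = True
    min_bout_duration_s: float = 0.0
    pamap2_label_map: dict = field(
        default_factory=lambda: dict(DEFAULT_PAMAP2_LABEL_MAP)
    )
    freq: FreqDetectorConfig = field(default_factory=FreqDetectorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if not self.window_seconds > 0:
            raise ValueError("window_seconds must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not self.target_rate_hz > 0:
            raise ValueError("target_rate_hz must be positive")
        if not self.static_rms_limit_mps2 > 0:
            raise ValueError("static_rms_limit_mps2 must be positive")

    @property
    def window_sz(self) -> int:
        return int(round(self.window_seconds * self.target_rate_hz))

    @property
    def hop(self) -> int:
        return int(round(self.window_sz * (1.0 - self.overlap_fraction)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["freq"]["locomotor_band_hz"] = list(self.freq.locomotor_band_hz)
        d["model"]["conv_kernel"] = list(self.model.conv_kernel)
        d["pamap2_label_map"] = {int(k): v for k, v in self.pamap2_label_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        freq = d.pop("freq", {})
        model = d.pop("model", {})
        training = d.pop("training", {})
        if "locomotor_band_hz" in freq:
            freq["locomotor_band_hz"] = tuple(freq["locomotor_band_hz"])
        if "conv_kernel" in model:
            model["conv_kernel"] = tuple(model["conv_kernel"])
        if "pamap2_label_map" in d:
            d["pamap2_label_map"] = {
                int(k): v for k, v in d["pamap2_label_map"].items()
            }
        return cls(
            freq=FreqDetectorConfig(**freq),
            model=ModelConfig(**model),
            training=TrainingConfig(**training),
            **d,
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)
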