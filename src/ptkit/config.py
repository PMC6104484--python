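"""Pipeline configuration: one TOML file drives every stage.

Every field defaults to the algorithm's published operating point
(5 Hz / 4th-order low pass, N = 128 statistics window, 1e-5 rad^2/s^2
bias latch, stationarity thresholds (0.05, 0.01, 0.01), Coiflet-5
levels 3/10, peak height and prominence 0.1, feedback gains (0, 0.5),
0.1 m displacement threshold).  Unknown keys are rejected so that a
typo in a config file cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field

from .errors import ParameterError, ValidationError


@dataclass
class PreprocessConfig:
    cutoff_hz: float = 5.0
    order: int = 4
    window: int = 128
    bias_var_threshold: float = 1e-5


@dataclass
class PostureConfig:
    accel_dev_thresh: float = 0.05
    accel_var_thresh: float = 0.01
    gyro_var_thresh: float = 0.01
    g0: float = 9.81
    min_sp_duration_s: float = 0.25
    wavelet: str = "coif5"
    j_lo: int = 3
    j_hi: int = 10


@dataclass
class FusionConfig:
    beta_sp: float = 0.5
    beta_ap: float = 0.0
    q0: tuple[float, float, float, float] = (
        1.0 / math.sqrt(2.0), 0.0, -1.0 / math.sqrt(2.0), 0.0
    )


@dataclass
class DetectConfig:
    height: float = 0.1
    prominence: float = 0.1
    merge_window_s: float = 1.0
    dz_threshold: float = 0.1
    max_search_s: float = 5.0


@dataclass
class EvaluateConfig:
    tolerance_s: float = 2.0


@dataclass
class SimulateConfig:
    duration_s: float = 600.0
    n_triplets: int = 10
    tilt_peak: float = 0.7
    rise_height: float = 0.25
    episode_duration_s: float = 2.0
    gyro_bias: tuple[float, float, float] = (0.01, 0.02, -0.01)
    noise_accel: float = 0.05
    noise_gyro: float = 0.01


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    posture: PostureConfig = field(default_factory=PostureConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    _POSITIVE = {
        ("preprocess", "cutoff_hz"),
        ("preprocess", "order"),
        ("preprocess", "window"),
        ("preprocess", "bias_var_threshold"),
        ("posture", "accel_dev_thresh"),
        ("posture", "accel_var_thresh"),
        ("posture", "gyro_var_thresh"),
        ("posture", "g0"),
        ("detect", "height"),
        ("detect", "prominence"),
        ("detect", "dz_threshold"),
        ("detect", "max_search_s"),
        ("evaluate", "tolerance_s"),
    }

    def validate(self) -> None:
        for section, key in self._POSITIVE:
            value = getattr(getattr(self, section), key)
            if not value > 0:
                raise ParameterError(f"[{section}] {key} must be positive, got {value}")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as f:
            data = tomllib.load(f)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for section, values in data.items():
            if not hasattr(cfg, section):
                raise ValidationError(f"unknown config section [{section}]")
            target = getattr(cfg, section)
            known = {f.name for f in dataclasses.fields(target)}
            for key, value in values.items():
                if key not in known:
                    raise ValidationError(f"unknown key {key!r} in [{section}]")
                current = getattr(target, key)
                if isinstance(current, tuple):
                    value = tuple(value)
                setattr(target, key, value)
        cfg.validate()
        return cfg

    def to_toml(self) -> str:
        """Serialize; parsing the result with from_toml round-trips."""
        lines = []
        for section_field in dataclasses.fields(self):
            section = section_field.name
            lines.append(f"[{section}]")
            target = getattr(self, section)
            for f in dataclasses.fields(target):
                value = getattr(target, f.name)
                lines.append(f"{f.name} = {_toml_value(value)}")
            lines.append("")
        return "\n".join(lines)


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (tuple, list)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    raise ValidationError(f"cannot serialize {value!r}")
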