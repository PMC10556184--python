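"""Pipeline configuration: defaults, YAML loading and exhaustive validation.

All defaults follow the recommended workflow: 500 ms maximum blink duration,
10 ms blink margins, 20 ms gap margins, ±3 SD outlier cut, downsampling to
100 Hz (factor 10 from a 1000 Hz recording), a 50 ms subtractive baseline
window at epoch onset, ±2 z-score trial exclusion, alpha .05, four folds,
1000 permutations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import TimeWindow
from .preprocess import BaselineSpec, BlinkParams

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised with every validation problem found, before any stage runs."""


@dataclass
class PipelineConfig:
    seed: int = 0
    protocol: dict = field(default_factory=dict)
    blink: dict = field(default_factory=dict)
    downsample_factor: int = 10
    calibration_file: str | None = None
    calibration_form: str = "power"
    pupil_column: str = "pupil_cue"
    x_column: str | None = "x_cue"
    y_column: str | None = "y_cue"
    condition: str | None = "condition"
    baseline_window: tuple = (0.0, 50.0)
    baseline_mode: str = "subtractive"
    z_thresh: float = 2.0
    qc: dict = field(default_factory=dict)
    method: str = "window"
    fixed: list = field(default_factory=lambda: ["condition"])
    coding: dict = field(default_factory=dict)
    random: str = "intercept"
    test_window: tuple | None = (750.0, 3000.0)
    alpha: float = 0.05
    n_permutations: int = 1000
    n_folds: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"unknown config field(s): {', '.join(sorted(unknown))}"
            )
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Check every field; raises ConfigError listing all problems."""
        errors = []
        if int(self.downsample_factor) != self.downsample_factor \
                or self.downsample_factor < 1:
            errors.append("downsample_factor must be a positive integer")
        try:
            self.blink_params()
        except (TypeError, ValueError) as exc:
            errors.append(f"blink: {exc}")
        try:
            self.baseline_spec()
        except (TypeError, ValueError) as exc:
            errors.append(f"baseline: {exc}")
        if self.z_thresh <= 0:
            errors.append("z_thresh must be > 0")
        if self.method not in ("window", "cluster", "crossval"):
            errors.append("method must be window, cluster or crossval")
        if not 0 < self.alpha < 1:
            errors.append("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            errors.append("n_permutations must be >= 100")
        if self.n_folds < 2:
            errors.append("n_folds must be >= 2")
        if self.method == "window" and self.test_window is None:
            errors.append("the window method requires test_window")
        if self.test_window is not None:
            try:
                TimeWindow(*self.test_window)
            except (TypeError, ValueError) as exc:
                errors.append(f"test_window: {exc}")
        if not self.fixed:
            errors.append("at least one fixed effect is required")
        if self.random not in ("intercept", "slopes"):
            errors.append("random must be 'intercept' or 'slopes'")
        if self.calibration_file is not None \
                and not Path(self.calibration_file).exists():
            errors.append(f"calibration_file not found: {self.calibration_file}")
        if errors:
            raise ConfigError("; ".join(errors))

    def blink_params(self) -> BlinkParams:
        return BlinkParams(**self.blink)

    def baseline_spec(self) -> BaselineSpec:
        return BaselineSpec(TimeWindow(*self.baseline_window),
                            self.baseline_mode)

    def to_dict(self) -> dict:
        return asdict(self)
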