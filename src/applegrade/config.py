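"""YAML run configuration.

One file configures the whole pipeline:

.. code-block:: yaml

    retinex:
      enabled: true
      sigma: 80.0
      epsilon: 1.0
      low_pct: 1.0
      high_pct: 99.0
    calibration:
      mm_per_px: 0.35
    thresholds:
      stem_conf_min: 0.5
      defect_conf_min: 0.5
      iou_min: 0.3
    grading: classical          # classical | stub
    stub:                       # only read when grading == stub
      frames: [...]             # scripted per-frame detections

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import CalibrationConfig

__all__ = ["RetinexConfig", "Thresholds", "RunConfig", "load_config"]


@dataclass(frozen=True)
class RetinexConfig:
    enabled: bool = True
    sigma: float = 80.0
    epsilon: float = 1.0
    low_pct: float = 1.0
    high_pct: float = 99.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("sigma and epsilon must be positive")
        if not (self.low_pct < self.high_pct):
            raise ValueError("need low_pct < high_pct")


@dataclass(frozen=True)
class Thresholds:
    stem_conf_min: float = 0.5
    defect_conf_min: float = 0.5
    iou_min: float = 0.3

    def __post_init__(self) -> None:
        for name in ("stem_conf_min", "defect_conf_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class RunConfig:
    retinex: RetinexConfig = field(default_factory=RetinexConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    grading: str = "classical"  # classical | stub
    stub: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grading not in ("classical", "stub"):
            raise ValueError(f"grading must be 'classical' or 'stub', got {self.grading!r}")


def _build(section_cls, data: dict, section: str):
    valid = set(section_cls.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")
    return section_cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; missing sections take their defaults."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"expected a YAML mapping in {path}")
            data = loaded
    if overrides:
        data = {**data, **overrides}
    known = {"retinex", "calibration", "thresholds", "grading", "stub"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        retinex=_build(RetinexConfig, data.get("retinex", {}), "retinex"),
        calibration=_build(CalibrationConfig, data.get("calibration", {}), "calibration"),
        thresholds=_build(Thresholds, data.get("thresholds", {}), "thresholds"),
        grading=data.get("grading", "classical"),
        stub=data.get("stub", {}),
    )
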