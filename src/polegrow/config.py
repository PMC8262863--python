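"""Pipeline configuration: validated parameters shared by all commands."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration value; the message carries a machine-readable
    ``code: detail`` form."""

    def __init__(self, code: str, detail: str):
        self.code = code
        super().__init__(f"{code}: {detail}")


@dataclass
class PipelineConfig:
    """All tunable parameters of the measurement pipeline.

    Units are µm (and minutes) throughout; pixels never leak into
    outputs.  ``channels`` maps channel names to page indices within a
    time point of a multi-page TIFF.
    """

    pixel_size: float = 0.065  # µm/px
    channels: dict = field(default_factory=lambda: {"phase": 0, "label": 1})
    frac: float = 0.2  # unlabeled threshold, fraction of per-cell max
    min_area: int = 80  # px
    max_area: int | None = None
    septa_prominence_frac: float = 0.3
    septa_pole_exclusion: float = 0.4  # µm
    pole_window: float = 0.5  # µm, brightest-pole integration window
    grid_step: float = 0.065  # µm, mean-profile grid
    max_distance: float = 2.0  # µm, mean-profile extent
    band_halfwidth: float = 0.65  # µm, transverse averaging band
    seed: int = 0
    out_dir: str = "out"

    def validate(self) -> "PipelineConfig":
        if not (0.0 < self.frac < 1.0):
            raise ConfigError("E_FRAC", f"frac must be in (0,1), got {self.frac}")
        if self.pixel_size <= 0:
            raise ConfigError("E_PIXEL_SIZE", "pixel_size must be > 0")
        if len(set(self.channels.values())) != len(self.channels):
            raise ConfigError("E_CHANNELS", "channel page indices must be unique")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError("E_CHANNELS", "channel names must be unique")
        if self.grid_step <= 0 or self.max_distance <= 0:
            raise ConfigError("E_GRID", "grid_step and max_distance must be > 0")
        return self

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load YAML or JSON config; keyword overrides win over the file,
        file values win over defaults."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("E_CONFIG", f"{path} does not contain a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError("E_CONFIG", f"unknown keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
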