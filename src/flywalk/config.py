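"""Pipeline configuration: flat TOML-style key-value files.

All apparatus constants live here with their defaults: camera at 95 mm with
a 50 degree horizontal field of view at VGA resolution, mirrors at 39
degrees to the chamber back wall, 100 um triangulation tolerance, 2 mm
frame-to-frame walking gate, 15 s analysis windows.  Unknown keys are
rejected by name so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .geometry import ArenaGeometry, default_arena

__all__ = ["PipelineConfig", "ConfigError", "load_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


DEFAULTS: dict[str, float | int] = {
    "camera.distance_mm": 95.0,
    "camera.hfov_deg": 50.0,
    "camera.width": 640,
    "camera.height": 480,
    "mirror.angle_deg": 39.0,
    "mirror.apex_offset_mm": 25.0,
    "tube.radius_mm": 10.0,
    "tube.height_mm": 50.0,
    "triangulation.tolerance_mm": 0.1,
    "detection.threshold": 0.0,  # 0 = automatic (25% of frame range)
    "detection.min_area": 4,
    "tracking.gate_mm": 2.0,
    "tracking.max_gap": 0,
    "session.window_s": 15.0,
    "session.energy_k": 5.0,
    "session.min_separation_s": 5.0,
    "stats.hist_min": 0.0,
    "stats.hist_max": 20.0,
    "stats.hist_bins": 40,
    "simulator.fps": 10.0,
    "simulator.n_flies": 10,
    "simulator.duration_s": 90.0,
    "simulator.noise_px": 0.2,
    "simulator.phenotype": "control",
    "simulator.age_days": 2.0,
}

_INT_KEYS = {
    "camera.width", "camera.height", "detection.min_area", "tracking.max_gap",
    "stats.hist_bins", "simulator.n_flies",
}


def _flatten(d: dict, prefix: str = "") -> dict[str, object]:
    out: dict[str, object] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Validated flat configuration; access values via ``cfg["block.key"]``."""

    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(DEFAULTS)
        for k, v in self.values.items():
            if k not in DEFAULTS:
                raise ConfigError(f"unknown configuration key: {k!r}")
            if k in _INT_KEYS:
                if not isinstance(v, int):
                    raise ConfigError(f"key {k!r} must be an integer, got {v!r}")
            elif isinstance(DEFAULTS[k], float) and isinstance(v, (int, float)):
                v = float(v)
            elif type(v) is not type(DEFAULTS[k]):
                raise ConfigError(
                    f"key {k!r} must be {type(DEFAULTS[k]).__name__}, got {v!r}"
                )
            merged[k] = v
        object.__setattr__(self, "values", merged)

    def __getitem__(self, key: str):
        return self.values[key]

    def arena(self) -> ArenaGeometry:
        return default_arena(
            camera_distance_mm=self["camera.distance_mm"],
            hfov_deg=self["camera.hfov_deg"],
            width=self["camera.width"],
            height=self["camera.height"],
            mirror_angle_deg=self["mirror.angle_deg"],
            apex_offset_mm=self["mirror.apex_offset_mm"],
            tube_radius_mm=self["tube.radius_mm"],
            tube_height_mm=self["tube.height_mm"],
            tolerance_mm=self["triangulation.tolerance_mm"],
        )

    @property
    def detection_threshold(self) -> float | None:
        t = self["detection.threshold"]
        return None if t == 0 else float(t)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a flat TOML config file; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return PipelineConfig(values=_flatten(raw))
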