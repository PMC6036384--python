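"""YAML run configuration.

A config file holds up to four blocks — ``device``, ``segmentation``,
``simulation`` and ``evaluation`` — each overriding package defaults.
Unknown keys are rejected with the offending paths listed, and a stable
hash of the effective configuration is stamped into every output so runs
can be traced back to their settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .device_template import DeviceTemplate, build_template
from .segmentation import SegmentationConfig

__all__ = ["RunConfig", "ConfigError"]

_DEVICE_KEYS = {"base_sides", "apex_height", "marker_diameter", "marker_depth"}
_SEG_KEYS = {
    "size_window_ref", "size_window_candidate", "st_numerators",
    "match_tol_start", "match_tol_step", "match_tol_max",
    "smooth_histogram", "v_marker", "shape_max_mm",
}
_SIM_KEYS = {
    "preset", "in_plane_mm", "slice_thickness_mm", "slice_gap_mm",
    "scan_plane", "table_shift_mm", "fov_mm", "fov_center_mm",
    "noise_sigma", "signal_levels", "intensity_max", "supersample", "seed",
    "scene_seed", "n_blobs", "oblique_angles_deg", "shift_mm",
}
_EVAL_KEYS = {"replicates", "seed"}


class ConfigError(ValueError):
    """Invalid configuration (unknown keys or malformed values)."""


@dataclass
class RunConfig:
    device: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        try:
            with open(path) as f:
                raw = yaml.safe_load(f) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path!r}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path!r}: top level must be a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        bad = []
        known = {
            "device": _DEVICE_KEYS,
            "segmentation": _SEG_KEYS,
            "simulation": _SIM_KEYS,
            "evaluation": _EVAL_KEYS,
        }
        for block in raw:
            if block not in known:
                bad.append(block)
        for block, keys in known.items():
            sub = raw.get(block) or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"block {block!r} must be a mapping")
            bad.extend(f"{block}.{k}" for k in sub if k not in keys)
        if bad:
            raise ConfigError(f"unknown configuration keys: {', '.join(sorted(bad))}")
        return cls(
            device=dict(raw.get("device") or {}),
            segmentation=dict(raw.get("segmentation") or {}),
            simulation=dict(raw.get("simulation") or {}),
            evaluation=dict(raw.get("evaluation") or {}),
        )

    def template(self) -> DeviceTemplate:
        return build_template(**{k: _tuplify(v) for k, v in self.device.items()})

    def seg_config(self, t: DeviceTemplate) -> SegmentationConfig:
        return SegmentationConfig.from_template(
            t, **{k: _tuplify(v) for k, v in self.segmentation.items()}
        )

    def to_dict(self) -> dict:
        return {
            "device": self.device,
            "segmentation": self.segmentation,
            "simulation": self.simulation,
            "evaluation": self.evaluation,
        }

    @property
    def hash(self) -> str:
        """Stable short hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v
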