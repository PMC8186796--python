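"""Run configuration: schema-validated YAML for fluid, channel and flags."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import SchemaError
from .physics import (ChannelGeometry, FluidMedium, REYNOLDS_THRESHOLD,
                      G_STANDARD, dpbs_default, water_viscosity)

_FLUID_KEYS = {"density", "viscosity", "temperature"}
_CHANNEL_KEYS = {"radius", "gravity"}
_FLAG_KEYS = {"wall_correction", "reynolds_threshold"}
_VIDEO_KEYS = {"pixel_size", "fps", "timestamps", "polarity"}
_IMAGING_KEYS = {"voxel_size", "nucleus_diameter_um", "denoise_sigma_um",
                 "threshold_rel", "smooth_radius_um", "separate_counts",
                 "min_volume_um3", "mask_closing_um", "deconvolve",
                 "pixel_size"}
_STATS_KEYS = {"alpha", "k"}
_TOP_KEYS = {"fluid", "channel", "flags", "video", "imaging", "stats", "seed"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise SchemaError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated configuration shared by the CLI stages."""

    fluid: FluidMedium = field(default_factory=dpbs_default)
    channel: ChannelGeometry = field(default_factory=lambda: ChannelGeometry(5e-4))
    wall_correction: bool = False
    reynolds_threshold: float = REYNOLDS_THRESHOLD
    video: dict = field(default_factory=dict)
    imaging: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, _TOP_KEYS, "config")
        fluid_raw = dict(raw.get("fluid", {}))
        _check_keys(fluid_raw, _FLUID_KEYS, "fluid")
        if "viscosity" not in fluid_raw and "temperature" in fluid_raw:
            fluid_raw["viscosity"] = water_viscosity(fluid_raw["temperature"])
        if fluid_raw:
            fluid = FluidMedium(
                density=float(fluid_raw.get("density", 1005.0)),
                viscosity=float(fluid_raw["viscosity"]),
                temperature=fluid_raw.get("temperature"))
        else:
            fluid = dpbs_default()
        chan_raw = dict(raw.get("channel", {}))
        _check_keys(chan_raw, _CHANNEL_KEYS, "channel")
        channel = ChannelGeometry(radius=float(chan_raw.get("radius", 5e-4)),
                                  gravity=float(chan_raw.get("gravity", G_STANDARD)))
        flags = dict(raw.get("flags", {}))
        _check_keys(flags, _FLAG_KEYS, "flags")
        video = dict(raw.get("video", {}))
        _check_keys(video, _VIDEO_KEYS, "video")
        imaging = dict(raw.get("imaging", {}))
        _check_keys(imaging, _IMAGING_KEYS, "imaging")
        stats = dict(raw.get("stats", {}))
        _check_keys(stats, _STATS_KEYS, "stats")
        return cls(fluid=fluid, channel=channel,
                   wall_correction=bool(flags.get("wall_correction", False)),
                   reynolds_threshold=float(
                       flags.get("reynolds_threshold", REYNOLDS_THRESHOLD)),
                   video=video, imaging=imaging, stats=stats,
                   seed=int(raw.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise SchemaError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)
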