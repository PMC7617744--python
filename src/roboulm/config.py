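"""Run configuration: a serialisable description of one simulation study.

A run is reproducible bit-for-bit from the config plus its seed for the
deterministic stages, and statistically reproducible for the stochastic
ones.  Every output file family is stamped with the config hash so artefacts
from different configurations cannot be silently mixed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "config_hash"]


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


@dataclass
class SceneSection:
    seed: int = 0
    n_speckle: int = 400
    n_bubbles: int = 20
    channel_radius_mm: float = 0.1
    crossing_angle_deg: float = 30.0
    channel_depth_mm: float = 20.0
    flow_speed_mm_s: float = 1.0


@dataclass
class ProbeSection:
    center_frequency_mhz: float = 7.8
    sound_speed_m_s: float = 1540.0
    aperture_mm: tuple = (9.6, 10.6)
    fov_halfwidth_mm: float = 7.5


@dataclass
class ProtocolSection:
    kind: str = "single_speed"        # or "mixed"
    speed_mm_s: float = 5.0
    range_mm: float = 20.0
    n_round_trips: int = 2
    accel_mm_s2: float = 3.0
    dwell_s: float = 1.0
    direction: str = "lateral"        # lateral | elevational | arbitrary
    start_time_s: float = 1.0


@dataclass
class LoopSection:
    volume_rate_hz: float = 85.0
    duration_s: float = 15.0
    crop_size_mm: float = 12.5
    beamform_latency_s: float = 0.04
    registration_latency_s: tuple = (0.04, 0.3)
    robot_command_latency_s: tuple = (0.03, 0.25)
    latency_model: str = "proportional"  # or "uniform"
    tracking_enabled: bool = True
    measurement: str = "image"        # image | truth
    noise_sigma: float = 0.02


@dataclass
class ReconSection:
    pitch_mm: float = 0.1
    frame_rate_hz: float = 20.0
    duration_s: float = 6.0
    noise_floor_rel: float = 3.0      # x background std
    ncc_threshold: float = 0.5
    upsample: int = 5
    persistence_frames: int = 4
    max_link_speed_mm_s: float = 10.0
    map_pitch_mm: float = 0.02


@dataclass
class RunConfig:
    scene: SceneSection = field(default_factory=SceneSection)
    probe: ProbeSection = field(default_factory=ProbeSection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    loop: LoopSection = field(default_factory=LoopSection)
    recon: ReconSection = field(default_factory=ReconSection)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for section, value in d.items():
            if not hasattr(cfg, section):
                raise ConfigError(f"unknown config section: {section!r}")
            current = getattr(cfg, section)
            if dataclasses.is_dataclass(current):
                names = {f.name for f in dataclasses.fields(current)}
                for k, v in value.items():
                    if k not in names:
                        raise ConfigError(f"unknown config key: {section}.{k}")
                    if isinstance(getattr(current, k), tuple) and isinstance(v, list):
                        v = tuple(v)
                    setattr(current, k, v)
            else:
                setattr(cfg, section, value)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def hash(self) -> str:
        return config_hash(self)


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]
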