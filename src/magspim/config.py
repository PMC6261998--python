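"""Experiment configuration: a flat, YAML-serialisable parameter record.

All parameter constraints of the owning modules are enforced at load time
by actually constructing the phantom and optics objects, so an invalid
config is rejected before any computation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, InvalidParameterError
from .phantom import EmbryoPhantom, OpticsModel, make_phantom

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    # phantom
    sphere_radius: float = 110.0
    n_nuclei: int = 300
    cap_half_angle: float = 80.0
    nucleus_radius: float = 8.0
    peak_intensity: float = 3000.0
    # optics
    attenuation_length: float = 80.0
    blur_sigma0: float = 2.0
    blur_growth: float = 0.06
    background_mean: float = 100.0
    background_sd: float = 2.0
    dual_sided_illumination: bool = True
    # acquisition grid
    shape: tuple = (64, 128, 128)
    pixel_size: float = 4.0
    plane_spacing: float = 4.0
    # quality analysis
    entropy_radius: int = 5
    corner_size: int = 30  # 100 px corners would overlap the embryo on 128 px frames
    # views
    tube_angles: tuple = (0.0, 45.0, 180.0, 225.0)
    # reproducibility / output
    seed: int = 0
    outdir: str = "magspim_out"

    def __post_init__(self):
        self.shape = tuple(int(v) for v in self.shape)
        self.tube_angles = tuple(float(v) for v in self.tube_angles)
        self.validate()

    def validate(self) -> None:
        try:
            self.optics()
            make_phantom(
                self.sphere_radius,
                min(self.n_nuclei, 1),
                self.cap_half_angle,
                seed=0,
                nucleus_radius=self.nucleus_radius,
                peak_intensity=self.peak_intensity,
            )
        except InvalidParameterError as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ConfigError("shape must be three positive integers (nz, ny, nx)")
        if self.pixel_size <= 0 or self.plane_spacing <= 0:
            raise ConfigError("spacings must be positive")
        if self.entropy_radius < 1 or self.corner_size < 1:
            raise ConfigError("entropy_radius and corner_size must be >= 1")
        if self.n_nuclei < 0:
            raise ConfigError("n_nuclei must be non-negative")

    # -- derived objects ---------------------------------------------------
    def phantom(self) -> EmbryoPhantom:
        return make_phantom(
            self.sphere_radius,
            self.n_nuclei,
            self.cap_half_angle,
            seed=self.seed,
            nucleus_radius=self.nucleus_radius,
            peak_intensity=self.peak_intensity,
        )

    def optics(self) -> OpticsModel:
        return OpticsModel(
            attenuation_length=float(self.attenuation_length),
            blur_sigma0=self.blur_sigma0,
            blur_growth=self.blur_growth,
            background_mean=self.background_mean,
            background_sd=self.background_sd,
            dual_sided_illumination=self.dual_sided_illumination,
        )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        d["tube_angles"] = list(self.tube_angles)
        if np.isinf(d["attenuation_length"]):
            d["attenuation_length"] = ".inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("attenuation_length") in (".inf", "inf"):
            d["attenuation_length"] = np.inf
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)
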