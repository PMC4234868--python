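"""Validated pipeline configuration (YAML on disk, pydantic in memory)."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .optics import (
    Layer,
    LayeredModel,
    OpticalProperties,
    ProbeGeometry,
    ScanSchedule,
)
from .synth import FactorTargets, GeneratorConfig

logger = logging.getLogger(__name__)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayerSection(_Section):
    mu_a: float
    mu_s_reduced: float
    g: float = 0.9
    n: float = 1.38
    thickness_mm: float

    def build(self) -> Layer:
        return Layer(
            OpticalProperties(self.mu_a, self.mu_s_reduced, self.g, self.n),
            self.thickness_mm,
        )


class ProbeSection(_Section):
    fiber_diameter_um: float = 200.0
    separation_um: float = 200.0
    acceptance_cos_min: float = 0.5

    def build(self) -> ProbeGeometry:
        return ProbeGeometry(
            self.fiber_diameter_um, self.separation_um, self.acceptance_cos_min
        )


class ScheduleSection(_Section):
    coarse_stop_mm: float = 4.0
    fine_stop_mm: float = 6.0
    coarse_step_mm: float = 0.2
    fine_step_mm: float = 0.1

    def build(self) -> ScanSchedule:
        return ScanSchedule.two_step(
            self.coarse_stop_mm,
            self.fine_stop_mm,
            self.coarse_step_mm,
            self.fine_step_mm,
        )


def _default_layers() -> list[LayerSection]:
    return [
        LayerSection(mu_a=0.41, mu_s_reduced=17.23, thickness_mm=5.0),
        LayerSection(mu_a=0.21, mu_s_reduced=12.02, thickness_mm=2.0),
    ]


class MCSection(_Section):
    layers: list[LayerSection] = Field(default_factory=_default_layers)
    probe: ProbeSection = Field(default_factory=ProbeSection)
    schedule: ScheduleSection = Field(default_factory=ScheduleSection)
    photons: int = Field(default=100_000, ge=1)
    seed: int = 1

    def build_model(self) -> LayeredModel:
        return LayeredModel(tuple(l.build() for l in self.layers))


class ProfileSection(_Section):
    flat_min_mm: float = 1.5
    flat_max_mm: float = 3.5
    k: float = Field(default=2.0, gt=0)
    boundary_mm: float = 5.0


class SpectraSection(_Section):
    area_lo_nm: float = 340.0
    area_hi_nm: float = 1020.0
    slope_lo_nm: float = 500.0
    slope_hi_nm: float = 550.0
    slope_scale: float = 1000.0
    expected_replicates: int = Field(default=20, ge=1)


class ThresholdsSection(_Section):
    test: str = "kruskal"
    alpha: float = Field(default=0.05, gt=0, lt=1)


class SyntheticSection(_Section):
    boundary_mm: float = 5.0
    total_depth_mm: float = 6.0
    detection_depth_mm: float = 0.6
    replicates: int = Field(default=20, ge=1)
    noise_sd: float = Field(default=0.02, ge=0)
    mixing: str = "linear"
    seed: int = 0

    def build(self, spectra: SpectraSection, schedule: ScheduleSection) -> GeneratorConfig:
        return GeneratorConfig(
            boundary_mm=self.boundary_mm,
            total_depth_mm=self.total_depth_mm,
            detection_depth_mm=self.detection_depth_mm,
            schedule=schedule.build(),
            replicates=self.replicates,
            noise_sd=self.noise_sd,
            slope_scale=spectra.slope_scale,
            mixing=self.mixing,
        )


class PipelineConfig(_Section):
    mc: MCSection = Field(default_factory=MCSection)
    profile: ProfileSection = Field(default_factory=ProfileSection)
    spectra: SpectraSection = Field(default_factory=SpectraSection)
    thresholds: ThresholdsSection = Field(default_factory=ThresholdsSection)
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)

    @model_validator(mode="after")
    def _cross_checks(self) -> "PipelineConfig":
        for layer in self.mc.layers:
            layer.build()  # raises InvalidParameterError with the field value
        self.mc.probe.build()
        sched = self.mc.schedule.build()
        model = self.mc.build_model()
        if sched.depths_mm[-1] >= model.total_thickness_mm:
            raise ValueError("mc.schedule extends beyond the layered model")
        return self

    def digest(self) -> str:
        """Stable hash of the fully resolved configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` yields all defaults.

    Unknown keys and invalid values raise ``ConfigError`` naming the field.
    The fully resolved config is echoed to the log.
    """
    if path is None:
        cfg = PipelineConfig()
    else:
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            cfg = PipelineConfig.model_validate(raw)
        except (ValidationError, ValueError) as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc
    logger.info("resolved config (digest %s): %s", cfg.digest(), cfg.model_dump())
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(), sort_keys=True), encoding="utf-8"
    )
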