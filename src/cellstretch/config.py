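"""Validated run configuration (YAML-backed).

A :class:`RunConfig` bundles everything a simulation run needs — template
geometry, wall material, stretch protocol and solver settings — and
round-trips losslessly through YAML.  Unknown keys are rejected.  Defaults
follow the standard study conditions: isotropic E = 100 MPa walls, ν = 0,
turgor P = 0.5 MPa.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .materials import MaterialParams
from .solver import SolverOptions
from .template import TemplateSpec
from .extensometer import StretchProtocol

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TemplateConfig(_Strict):
    cell_width: float = 20.0
    aspect_ratio: float = 5.0
    staggered: bool = True
    template_extent: tuple[float, float] = (300.0, 300.0)
    vertex_spacing: float = 2.0
    extrusion_segments: int = 5
    segment_length: float = 4.0
    anticlinal_depth: float = 20.0
    connection_band_fraction: float = 1.0 / 3.0
    wall_thickness: float = 1.1
    smoothing_iterations: int = 10
    rng_seed: int = 0

    def to_spec(self) -> TemplateSpec:
        return TemplateSpec(**self.model_dump())

    @model_validator(mode="after")
    def _check(self):
        self.to_spec()  # dataclass invariants
        return self


class MaterialConfig(_Strict):
    strain_measure: str = "biot"
    E_long: float = 100.0
    E_trans: float = 100.0
    E_normal: float | None = None
    poisson: float = 0.0
    #: optional per-wall-type Young's modulus overrides (isotropic walls),
    #: keyed by wall-type name, e.g. {"outer-periclinal": 150.0}
    wall_moduli: dict[str, float] = Field(default_factory=dict)

    def to_params(self) -> MaterialParams:
        return MaterialParams(E_long=self.E_long, E_trans=self.E_trans,
                              E_normal=self.E_normal, poisson=self.poisson,
                              strain_measure=self.strain_measure)

    @model_validator(mode="after")
    def _check(self):
        self.to_params()
        return self


class ProtocolConfig(_Strict):
    direction: str = "longitudinal"
    total_strain: float = 0.5
    steps: int = 25
    pressure: float = 0.5

    def to_protocol(self) -> StretchProtocol:
        return StretchProtocol(**self.model_dump())

    @model_validator(mode="after")
    def _check(self):
        self.to_protocol()
        return self


class SolverConfig(_Strict):
    tol: float = 1e-4
    dt0: float = 0.1
    dt_max: float = 1e6
    max_iter: int = 60
    fd_step: float = 1e-5
    hessian_lag: int = 1

    def to_options(self) -> SolverOptions:
        return SolverOptions(tol=self.tol, dt0=self.dt0, dt_max=self.dt_max,
                             max_iter=self.max_iter, fd_step=self.fd_step,
                             hessian_lag=self.hessian_lag)


class RunConfig(_Strict):
    """Top-level, serializable run description."""

    schema_version: int = 1
    template: TemplateConfig = Field(default_factory=TemplateConfig)
    material: MaterialConfig = Field(default_factory=MaterialConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    output_dir: str = "results"
    rng_seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return RunConfig.from_yaml(path)
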