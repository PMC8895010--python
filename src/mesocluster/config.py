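"""Pipeline configuration: measured constants and stage settings.

A :class:`PipelineConfig` collects the experimentally determined
constants that the derived-constant chain consumes.  Loading from YAML
validates units and signs and rejects unknown keys outright — a typo in
a key should fail loudly, not silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import constants as k
from .errors import ConfigError

#: Stages the end-to-end chain may run, in order.
ALL_STAGES = ("hydrodynamics", "reaction_diffusion", "cluster_dynamics", "speciation")


@dataclass(frozen=True)
class PipelineConfig:
    temperature: float = k.DEFAULT_TEMPERATURE  # [K]
    molar_mass: float = k.DEFAULT_MOLAR_MASS  # [g mol⁻¹]
    viscosity: float = k.DEFAULT_VISCOSITY  # [Pa s]
    cluster_diameter: float = k.DEFAULT_CLUSTER_DIAMETER  # [m]; radius = diameter/2
    d1: float = k.DEFAULT_D1  # monomer diffusion coefficient [m² s⁻¹]
    r1: float = k.DEFAULT_R1  # monomer hydrodynamic radius [m]
    r2: float = k.DEFAULT_R2  # dimer hydrodynamic radius [m]
    k_D: float = k.DEFAULT_KD  # dimerization constant [M⁻¹]
    drive: float = 1.0 / 3.0  # radius-equation growth-drive coefficient σ_d
    shrink: float = 1.0  # radius-equation shrink coefficient χ
    speciation_conc: float = 0.5  # concentration for the speciation report [M]
    r0: float = 1e-9  # initial cluster radius for the trajectory [m]
    t_end: float = 1e-3  # trajectory horizon [s]
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self):
        positive = ("temperature", "molar_mass", "viscosity", "cluster_diameter",
                    "d1", "r1", "r2", "speciation_conc", "r0", "t_end")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"config field {name!r} must be positive")
        if self.k_D < 0 or self.drive < 0 or self.shrink < 0:
            raise ConfigError("k_D, drive and shrink must be nonnegative")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        object.__setattr__(self, "stages", tuple(self.stages))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must be a mapping of key: value pairs")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d
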