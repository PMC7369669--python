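"""Run configuration: TOML schema, validation, and defaults.

The default configuration reproduces the baseline hypoxia-recovery
experiment verbatim: the 1.8 mm perforated square with 32+32 holes, the
Stokes velocity pre-solve, inlet/outlet Robin data (9.2 / 8.2 mM), hypoxic
initial state (phi0 = 4 mM, theta0 = 0.01 mM), dt = 0.25 s and 20 Picard
sweeps per step.  An empty TOML file therefore runs the full baseline
experiment.  Unknown keys are rejected, and every override is echoed into
the output metadata.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .kinetics import ModelParameters

__all__ = ["RunConfiguration", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PhysicsConfig:
    sigma: float = 0.03
    alpha: float = 2.2e-3
    beta: float = 2.4e-3
    a: float = 39.0
    b: float = 9.2
    psi_H: float = 3.6e-2
    r: float = 2.73
    mu0: float = 0.08
    theta50: float = 5e-5

    def to_parameters(self) -> ModelParameters:
        try:
            return ModelParameters(**dataclasses.asdict(self))
        except ValueError as exc:
            raise ConfigError(f"physics: {exc}") from exc


@dataclass
class GeometryConfig:
    side: float = 1.8
    n_inlets: int = 32
    n_outlets: int = 32
    hole_radius: float = 0.03
    layout: str = "checkerboard"
    seed: int = 0


@dataclass
class StokesConfig:
    enabled: bool = True
    edge_velocity: tuple = (0.0, 0.6)
    inlet_speed: float = 3.4
    outlet_speed: float = 1.7
    penalty: float = 1e-6
    stabilization: float = 0.05


@dataclass
class NumericsConfig:
    n_edge_segments: int = 60
    n_hole_segments: int = 8
    dt: float = 0.25
    n_picard: int = 20
    t_final: float = 10.0
    phi_max: float = 12.0
    n_knots: int = 800


@dataclass
class BoundaryConfig:
    gamma_multiplier: float = 1000.0
    delta_multiplier: float = 1000.0
    phi_b: dict = field(default_factory=lambda: {
        "inlet": 9.2, "outlet": 8.2, "edge": 8.2})


@dataclass
class InitialConfig:
    phi0: float = 4.0
    theta0: float = 0.01


@dataclass
class OutputConfig:
    directory: str = "out"
    snapshot_every: int = 1
    figure_times: tuple = (1.0, 2.0, 3.0, 7.0)


_SECTIONS = {
    "physics": PhysicsConfig,
    "geometry": GeometryConfig,
    "stokes": StokesConfig,
    "numerics": NumericsConfig,
    "boundary": BoundaryConfig,
    "initial": InitialConfig,
    "output": OutputConfig,
}


@dataclass
class RunConfiguration:
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    stokes: StokesConfig = field(default_factory=StokesConfig)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    boundary: BoundaryConfig = field(default_factory=BoundaryConfig)
    initial: InitialConfig = field(default_factory=InitialConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    # programmatic overrides (bypass geometry / Stokes stages)
    mesh: object = None
    velocity: object = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = self.numerics
        for key, val, cond in (
            ("numerics.dt", n.dt, n.dt > 0),
            ("numerics.t_final", n.t_final, n.t_final >= 0),
            ("numerics.n_picard", n.n_picard, n.n_picard >= 1),
            ("numerics.n_edge_segments", n.n_edge_segments,
             n.n_edge_segments >= 1),
            ("numerics.n_hole_segments", n.n_hole_segments,
             n.n_hole_segments >= 3),
            ("numerics.phi_max", n.phi_max, n.phi_max > 0),
            ("numerics.n_knots", n.n_knots, n.n_knots >= 16),
            ("geometry.side", self.geometry.side, self.geometry.side > 0),
            ("geometry.hole_radius", self.geometry.hole_radius,
             self.geometry.hole_radius > 0),
            ("geometry.n_inlets", self.geometry.n_inlets,
             self.geometry.n_inlets >= 0),
            ("geometry.n_outlets", self.geometry.n_outlets,
             self.geometry.n_outlets >= 0),
            ("boundary.gamma_multiplier", self.boundary.gamma_multiplier,
             self.boundary.gamma_multiplier >= 0),
            ("boundary.delta_multiplier", self.boundary.delta_multiplier,
             self.boundary.delta_multiplier >= 0),
            ("output.snapshot_every", self.output.snapshot_every,
             self.output.snapshot_every >= 1),
        ):
            if not cond:
                raise ConfigError(
                    f"{key} must be {_constraint_text(key)} (got {val})")
        self.physics.to_parameters()  # validates physics incl. sigma < 1
        for cls in ("inlet", "outlet", "edge"):
            if cls not in self.boundary.phi_b:
                raise ConfigError(f"boundary.phi_b missing class {cls!r}")
            if self.boundary.phi_b[cls] < 0:
                raise ConfigError(f"boundary.phi_b[{cls!r}] must be >= 0")
            if self.boundary.phi_b[cls] > self.numerics.phi_max:
                raise ConfigError(
                    f"boundary.phi_b[{cls!r}] exceeds numerics.phi_max")

    def to_dict(self) -> dict:
        out = {}
        for name, cls in _SECTIONS.items():
            sec = dataclasses.asdict(getattr(self, name))
            out[name] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in sec.items()}
        return out

    def overrides(self) -> dict:
        """Keys that differ from the baseline defaults (echoed to metadata)."""
        base = RunConfiguration().to_dict()
        cur = self.to_dict()
        diff = {}
        for sec, vals in cur.items():
            for k, v in vals.items():
                if base[sec][k] != v:
                    diff[f"{sec}.{k}"] = v
        return diff


_CONSTRAINTS = {
    "numerics.dt": "> 0", "numerics.t_final": ">= 0",
    "numerics.n_picard": ">= 1", "numerics.n_edge_segments": ">= 1",
    "numerics.n_hole_segments": ">= 3", "numerics.phi_max": "> 0",
    "numerics.n_knots": ">= 16", "geometry.side": "> 0",
    "geometry.hole_radius": "> 0", "geometry.n_inlets": ">= 0",
    "geometry.n_outlets": ">= 0", "boundary.gamma_multiplier": ">= 0",
    "boundary.delta_multiplier": ">= 0", "output.snapshot_every": ">= 1",
}


def _constraint_text(key: str) -> str:
    return _CONSTRAINTS.get(key, "valid")


def load_config(path) -> RunConfiguration:
    """Load and validate a TOML run configuration.

    Missing keys take the baseline defaults; unknown sections or keys are
    rejected with the offending name.
    """
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    sections = {}
    for name, payload in raw.items():
        if name not in _SECTIONS:
            raise ConfigError(f"unknown section [{name}]")
        cls = _SECTIONS[name]
        fields = {f.name for f in dataclasses.fields(cls)}
        for key in payload:
            if key not in fields:
                raise ConfigError(f"unknown key {name}.{key}")
        payload = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in payload.items()}
        sections[name] = cls(**payload)
    return RunConfiguration(**sections)
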