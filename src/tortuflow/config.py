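"""Run configuration: a single YAML file whose defaults reproduce the
reference model (30 degree angle, one tortuous unit, 1 mm mesh interval,
0.156 m/s steady inlet, zero outlet gauge, 1e-3 convergence)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .geometry import VesselGeometry
from .solver import BoundaryConditionSet, FluidProperties, SolverConfig
from .waveforms import DEFAULT_ANCHORS, DEFAULT_PERIOD, build_waveform


class ConfigError(ValueError):
    """Malformed run configuration (unknown or invalid keys)."""


@dataclass(frozen=True)
class RunConfig:
    geometry: VesselGeometry = field(default_factory=VesselGeometry)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    bc: BoundaryConditionSet = field(default_factory=BoundaryConditionSet)
    solver: SolverConfig = field(default_factory=SolverConfig)
    interval_mm: float = 1.0
    mode: str = "steady"                       # "steady" | "pulsatile"
    waveform_anchors: tuple = DEFAULT_ANCHORS  # [(t, v_in, p_out), ...]
    waveform_period: float = DEFAULT_PERIOD
    output_dir: str = "tortuflow_out"
    verbosity: int = 1

    def __post_init__(self):
        if self.mode not in ("steady", "pulsatile"):
            raise ConfigError(f"mode must be 'steady' or 'pulsatile', got {self.mode!r}")
        if self.interval_mm <= 0:
            raise ConfigError("interval_mm must be positive")

    def waveform(self):
        return build_waveform(self.waveform_anchors, self.waveform_period)

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "fluid": dataclasses.asdict(self.fluid),
            "bc": dataclasses.asdict(self.bc),
            "solver": dataclasses.asdict(self.solver),
            "mesh": {"interval_mm": self.interval_mm},
            "mode": self.mode,
            "waveform": {"period": self.waveform_period,
                         "anchors": [list(a) for a in self.waveform_anchors]},
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
        }

    def to_yaml(self, fname) -> None:
        with open(fname, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in '{where}': {sorted(unknown)}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid '{where}' block: {exc}") from exc


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML file path, stream, or mapping.

    Unknown keys anywhere in the file are rejected.
    """
    if isinstance(source, dict):
        data = source
    elif hasattr(source, "read"):
        data = yaml.safe_load(source) or {}
    else:
        with open(source) as f:
            data = yaml.safe_load(f) or {}
    known = {"geometry", "fluid", "bc", "solver", "mesh", "mode",
             "waveform", "output_dir", "verbosity"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    geometry = _build(VesselGeometry, data.get("geometry", {}), "geometry")
    fluid = _build(FluidProperties, data.get("fluid", {}), "fluid")
    bc = _build(BoundaryConditionSet, data.get("bc", {}), "bc")
    solver = _build(SolverConfig, data.get("solver", {}), "solver")
    mesh = dict(data.get("mesh", {}))
    unknown = set(mesh) - {"interval_mm"}
    if unknown:
        raise ConfigError(f"unknown keys in 'mesh': {sorted(unknown)}")
    wf = dict(data.get("waveform", {}))
    unknown = set(wf) - {"period", "anchors"}
    if unknown:
        raise ConfigError(f"unknown keys in 'waveform': {sorted(unknown)}")
    anchors = tuple(tuple(a) for a in wf.get("anchors", DEFAULT_ANCHORS))
    return RunConfig(
        geometry=geometry, fluid=fluid, bc=bc, solver=solver,
        interval_mm=float(mesh.get("interval_mm", 1.0)),
        mode=data.get("mode", "steady"),
        waveform_anchors=anchors,
        waveform_period=float(wf.get("period", DEFAULT_PERIOD)),
        output_dir=str(data.get("output_dir", "tortuflow_out")),
        verbosity=int(data.get("verbosity", 1)),
    )
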