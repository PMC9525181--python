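"""Run configuration: a validated schema shared by the CLI commands.

The configuration is a plain nested mapping (YAML/JSON on disk) validated
into frozen dataclasses before any computation starts.  Every stochastic
step's seed is part of the configuration and echoed into output metadata,
so any artifact bundle can be regenerated from its sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lpvar import DEFAULT_LAMBDA_GRID, DEFAULT_P_GRID, DEFAULT_Q_GRID

__all__ = ["SimulationConfig", "GridConfig", "EstimatorConfig", "CVConfig", "RunConfig"]


@dataclass(frozen=True)
class SimulationConfig:
    coupling_set: str = "I"
    f_L: float = 4.0
    f_H: float = 60.0
    fs: float = 240.0
    duration: float = 6.0
    driver_bandwidth: float = 1.0
    sigma_u: float = 0.5
    n_realizations: int = 20


@dataclass(frozen=True)
class GridConfig:
    phase_range: tuple[float, float] = (2.0, 10.0)
    phase_step: float = 1.0
    phase_width: float = 0.5
    amp_range: tuple[float, float] = (20.0, 80.0)
    amp_step: float = 2.0
    amp_width: float = 2.0


@dataclass(frozen=True)
class EstimatorConfig:
    method: str = "lpvar"
    p_grid: tuple[int, ...] = DEFAULT_P_GRID
    q_grid: tuple[int, ...] = DEFAULT_Q_GRID
    lam_init: float = 10.0
    lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_permutations: int = 1
    trim_edges: bool = False

    def __post_init__(self) -> None:
        from .cfc import METHODS

        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")


@dataclass(frozen=True)
class CVConfig:
    n_repeats: int = 50
    holdout_fraction: float = 0.10
    inner_folds: int = 5
    n_shuffles: int = 10


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    grids: GridConfig = field(default_factory=GridConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "simulation", "grids", "estimator", "cv",
            ):
                section_cls = {
                    "simulation": SimulationConfig,
                    "grids": GridConfig,
                    "estimator": EstimatorConfig,
                    "cv": CVConfig,
                }[f.name]
                valid = {sf.name for sf in dataclasses.fields(section_cls)}
                bad = set(value) - valid
                if bad:
                    raise ValueError(f"unknown keys in section '{f.name}': {sorted(bad)}")
                value = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                value = section_cls(**value)
            kwargs[f.name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
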