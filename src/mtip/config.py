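"""Run configuration: grids, iteration schedule, projector and shrinkwrap knobs.

Configs are plain dataclasses that round-trip through YAML; the CLI loads a
file, applies flag overrides and snapshots the result next to every run so a
run directory is self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import default_q_max
from .real_space import ProjectorSettings

__all__ = ["IterationSchedule", "ShrinkwrapSettings", "RunConfig", "load_config", "save_config"]


@dataclass
class IterationSchedule:
    """Counts of the iterative stage: outer cycles of HIO then ER blocks,
    one shrinkwrap per ``shrinkwrap_every`` outer cycles, then an ER-only
    refinement with frozen support."""

    outer_iter: int = 15
    hio_iterations: int = 60
    er_iterations: int = 40
    refine_iterations: int = 200
    shrinkwrap_every: int = 1

    def __post_init__(self) -> None:
        for name in ("outer_iter", "hio_iterations", "er_iterations", "refine_iterations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.shrinkwrap_every < 1:
            raise ValueError("shrinkwrap_every must be >= 1")

    @property
    def total_iterations(self) -> int:
        return (
            self.outer_iter * (self.hio_iterations + self.er_iterations)
            + self.refine_iterations
        )


@dataclass
class ShrinkwrapSettings:
    """Gaussian-smoothing support re-estimation schedule.

    sigma starts at ``sigma_factor`` radial steps, shrinks by ``decay`` at
    each call and never goes below ``floor_factor`` radial steps.
    """

    sigma_factor: float = 3.0
    decay: float = 0.99
    floor_factor: float = 1.5
    # Soft threshold: smooth (Gaussian-like) objects carry density tails well
    # below 10% of the peak that the correlation data still see; cutting them
    # pins the data residual far above its attainable level.
    threshold_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma_factor <= 0 or self.floor_factor <= 0:
            raise ValueError("sigma factors must be positive")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must lie in (0, 1]")
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must lie in (0, 1)")


@dataclass
class RunConfig:
    """Everything a reconstruction run needs, serializable to YAML."""

    n_shells: int = 16
    r_max: float = 1.0
    q_max: float | None = None  # None -> pi*N/(2*r_max)
    schedule: IterationSchedule = field(default_factory=IterationSchedule)
    projector: ProjectorSettings = field(default_factory=ProjectorSettings)
    shrinkwrap: ShrinkwrapSettings = field(default_factory=ShrinkwrapSettings)
    n_replicas: int = 10
    seeds: list[int] | None = None  # None -> base_seed + replica index
    base_seed: int = 0
    even_only: bool = True
    initial_support_frac: float = 0.8
    output_dir: str = "mtip_run"
    log_level: str = "INFO"

    def resolved_q_max(self) -> float:
        return self.q_max if self.q_max is not None else default_q_max(self.n_shells, self.r_max)

    def replica_seeds(self) -> list[int]:
        if self.seeds is not None:
            if len(self.seeds) < self.n_replicas:
                raise ValueError("fewer seeds than replicas")
            return [int(s) for s in self.seeds[: self.n_replicas]]
        return [self.base_seed + i for i in range(self.n_replicas)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "schedule" in d and isinstance(d["schedule"], dict):
            d["schedule"] = IterationSchedule(**d["schedule"])
        if "projector" in d and isinstance(d["projector"], dict):
            d["projector"] = ProjectorSettings(**d["projector"])
        if "shrinkwrap" in d and isinstance(d["shrinkwrap"], dict):
            d["shrinkwrap"] = ShrinkwrapSettings(**d["shrinkwrap"])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
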