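"""Run configuration: one validated, hashable object for the whole
simulate -> process -> fit -> stats workflow, serialisable to YAML/JSON."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import ClassEffect, SimulationConfig

__all__ = ["RunConfig", "ProcessingOptions", "HrfOptions", "StatsOptions"]


@dataclass(frozen=True)
class DesignOptions:
    n_norm: int = 31
    n_glaucoma: int = 43
    n_mixed: int = 12

    def __post_init__(self) -> None:
        if min(self.n_norm, self.n_glaucoma, self.n_mixed) < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.n_norm + self.n_glaucoma + self.n_mixed < 1:
            raise ValueError("cohort must contain at least one subject")


@dataclass(frozen=True)
class ProcessingOptions:
    rise_frac: float = 0.80
    fall_frac: float = 0.01
    gates: list | None = None  # None = default gates relative to peak
    max_condition: float = 1e3

    def __post_init__(self) -> None:
        if not (0 < self.fall_frac < self.rise_frac < 1):
            raise ValueError("need 0 < fall_frac < rise_frac < 1")


@dataclass(frozen=True)
class HrfOptions:
    shape: float = 5.0
    max_tau_s: float = 20.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.max_tau_s <= 0:
            raise ValueError("shape and max_tau_s must be > 0")


@dataclass(frozen=True)
class StatsOptions:
    working_correlation: str = "exchangeable"
    n_boot: int = 1000
    alpha: float = 0.05
    with_c_ci: bool = True

    def __post_init__(self) -> None:
        if self.working_correlation not in ("exchangeable", "independence"):
            raise ValueError(
                f"unknown working correlation {self.working_correlation!r}"
            )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_boot < 500:
            raise ValueError("n_boot must be >= 500")


def _build(cls, data: dict, path: str):
    """Construct a (nested) dataclass from a mapping, rejecting unknown
    keys so configuration typos fail loudly."""
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    import typing

    hints = typing.get_type_hints(cls)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        t = hints.get(key)
        if dataclasses.is_dataclass(t) and isinstance(t, type):
            kwargs[key] = _build(t, value, f"{path}.{key}")
        else:
            kwargs[key] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters of one pipeline run.

    ``seed`` drives every stochastic stage (simulation and bootstrap);
    it is mandatory and has no default.
    """

    seed: int
    design: DesignOptions = field(default_factory=DesignOptions)
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    processing: ProcessingOptions = field(default_factory=ProcessingOptions)
    hrf: HrfOptions = field(default_factory=HrfOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        # validate simulation overrides eagerly
        self.simulation_config()

    def simulation_config(self) -> SimulationConfig:
        over = dict(self.simulation)
        unknown = set(over) - {
            f.name for f in dataclasses.fields(SimulationConfig)
        }
        if unknown:
            raise ValueError(f"simulation: unknown keys {sorted(unknown)}")
        if "effects" in over:
            over["effects"] = {
                ch: {cls: ClassEffect(**e) if isinstance(e, dict) else e
                     for cls, e in d.items()}
                for ch, d in over["effects"].items()
            }
        return SimulationConfig(seed=self.seed, **over)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, "config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @property
    def config_hash(self) -> str:
        """Short digest of the canonical JSON form, stamped on outputs."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
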