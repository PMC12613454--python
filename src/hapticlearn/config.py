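"""Structured run configuration with YAML round-trip.

Every physical constant, protocol index, guidance setting and behavioral
coupling lives here, so a YAML snapshot plus a master seed fully determines
every output byte of a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from typing import Any

import yaml

from .cohort import EffectConfig
from .pendulum import PendulumParams
from .protocol import ProtocolConfig

__all__ = ["GuidanceConfig", "SimConfig", "StudyConfig"]


@dataclass(frozen=True)
class GuidanceConfig:
    kp: float = 75.0  # N/m
    kd: float = 15.0  # N s/m
    #: reference planner used inside study simulation runs; "minjerk" is the
    #: closed-form swing-compensated planner, "optimal" the shooting optimizer
    planner: str = "minjerk"
    horizon: float = 1.0  # s, the inter-wall interval
    w_acc: float = 1.0e4
    w_stab: float = 1.0
    w_u: float = 1.0e-3
    n_nodes: int = 20


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.002  # batch-engine integrator step (s)
    n_lin_steps: int = 50  # internal-planner prediction grid
    move_frac: float = 0.8  # min-jerk move time / wall interval


@dataclass(frozen=True)
class StudyConfig:
    n_participants: int = 40
    pendulum: PendulumParams = field(default_factory=PendulumParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    guidance: GuidanceConfig = field(default_factory=GuidanceConfig)
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict[str, Any]:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        return _fromdict(cls, d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _asdict(obj: Any) -> Any:
    if is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_asdict(v) for v in obj]
    return obj


def _fromdict(cls: type, d: Any) -> Any:
    if not is_dataclass(cls):
        return d
    import typing

    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        ftype = hints.get(f.name)
        if isinstance(ftype, type) and is_dataclass(ftype):
            kwargs[f.name] = _fromdict(ftype, v)
        elif isinstance(v, list):
            kwargs[f.name] = tuple(v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)
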