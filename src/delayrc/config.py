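"""Structured run configuration and deterministic artifact serialization.

Configurations are nested key/value YAML; every omitted key falls back to
the published default, unknown keys are rejected by name, and a loaded
configuration plus its single ``seed_base`` reproduces a run bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dde import MGParams
from .exceptions import ConfigurationError
from .model import FeedbackReservoirResults, PhaseSchedule, ReservoirConfig

__all__ = ["RunConfig", "load_config", "save_config", "write_trace", "read_trace"]


@dataclass
class ReservoirSettings:
    gamma: float = 0.01
    eta: float = 0.5
    rho: float = 1.0
    denom_guard: float = 1e-6
    n: int = 300
    tau: float = 600.0
    grid: int = 600
    mu: float = 0.1


@dataclass
class ScheduleSettings:
    offset: int = 50
    teacher_forcing: int = 50000
    training: int = 10000
    validation: int = 10000


@dataclass
class TaskSettings:
    experiment: str = "exp1"
    cue_duration: int = 5
    gap_tf: tuple = (50, 400)
    gap: tuple = (100, 800)
    levels: tuple = (18.0, 10.0)
    constant: float = 5.0
    sine_amplitude: float = 1.0
    sine_period: float = 100.0
    sine_mean: float = 1.0 / 3.0
    noise_lo: float = -5.0
    noise_hi: float = 15.0
    filter_std: float = 5.0
    ramps: tuple = (300, 600)
    ramp_levels: tuple = (9.0, 5.0)


@dataclass
class ReadoutSettings:
    ridge: float = 0.0
    noise_scale: float | None = None  # None -> 1% of target peak-to-peak


@dataclass
class StabilitySettings:
    margin: float | None = None  # None -> half the feedback level gap
    max_steps: int = 50000
    cue_test: int = 1000


@dataclass
class RunConfig:
    reservoir: ReservoirSettings = field(default_factory=ReservoirSettings)
    schedule: ScheduleSettings = field(default_factory=ScheduleSettings)
    task: TaskSettings = field(default_factory=TaskSettings)
    readout: ReadoutSettings = field(default_factory=ReadoutSettings)
    stability: StabilitySettings = field(default_factory=StabilitySettings)
    seed_base: int = 0
    outdir: str = "runs"
    verbosity: str = "info"

    # -- builders -----------------------------------------------------------
    def build_reservoir(self) -> ReservoirConfig:
        r = self.reservoir
        return ReservoirConfig(
            mg=MGParams(
                gamma=r.gamma, eta=r.eta, rho=r.rho, denom_guard=r.denom_guard
            ),
            n=r.n,
            tau=r.tau,
            grid=r.grid,
            mu=r.mu,
        )

    def build_schedule(self) -> PhaseSchedule:
        s = self.schedule
        return PhaseSchedule(
            offset=s.offset,
            teacher_forcing=s.teacher_forcing,
            training=s.training,
            validation=s.validation,
        )

    def task_params(self) -> dict:
        t = self.task
        return {
            "cue_duration": t.cue_duration,
            "gap_tf": tuple(t.gap_tf),
            "gap": tuple(t.gap),
            "levels": tuple(t.levels),
            "constant": t.constant,
            "sine_amplitude": t.sine_amplitude,
            "sine_period": t.sine_period,
            "sine_mean": t.sine_mean,
            "noise_range": (t.noise_lo, t.noise_hi),
            "filter_std": t.filter_std,
            "ramps": tuple(t.ramps),
            "ramp_levels": tuple(t.ramp_levels),
        }

    def validate(self) -> "RunConfig":
        self.build_reservoir()
        self.build_schedule()
        if self.task.cue_duration < 1:
            raise ConfigurationError("task.cue_duration must be >= 1")
        for key in ("gap_tf", "gap"):
            lo, hi = getattr(self.task, key)
            if lo > hi or lo <= self.task.cue_duration:
                raise ConfigurationError(
                    f"task.{key} range [{lo}, {hi}] must satisfy "
                    f"cue_duration < lo <= hi"
                )
        if self.readout.ridge < 0:
            raise ConfigurationError("readout.ridge must be >= 0")
        if self.readout.noise_scale is not None and self.readout.noise_scale < 0:
            raise ConfigurationError("readout.noise_scale must be >= 0")
        return self

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {
                    f.name: conv(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)


_TUPLE_FIELDS = {"gap_tf", "gap", "levels", "ramps", "ramp_levels"}


def _merge(dc, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"expected a mapping at '{path or '<root>'}'")
    names = {f.name: f for f in dataclasses.fields(dc)}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in names:
            raise ConfigurationError(f"unknown configuration key '{where}'")
        current = getattr(dc, key)
        if dataclasses.is_dataclass(current):
            _merge(current, value, where)
            continue
        if key in _TUPLE_FIELDS:
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ConfigurationError(
                    f"configuration key '{where}' must be a 2-element list"
                )
            value = tuple(value)
        elif current is not None and not isinstance(
            value, type(current)
        ) and not (isinstance(current, float) and isinstance(value, int)):
            raise ConfigurationError(
                f"configuration key '{where}' has type "
                f"{type(value).__name__}, expected {type(current).__name__}"
            )
        setattr(dc, key, value)


def load_config(path) -> RunConfig:
    """Load, default-fill and validate a YAML run configuration.

    An empty file yields the full published defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    cfg = RunConfig()
    _merge(cfg, data, "")
    return cfg.validate()


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def write_trace(result: FeedbackReservoirResults, path) -> None:
    """Per-step columnar trace table; full float precision, fixed order."""
    try:
        result.traces.to_csv(path, index=False)
    except OSError as exc:
        raise ConfigurationError(f"cannot write trace to '{path}': {exc}") from exc


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)
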