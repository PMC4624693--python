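"""Run configuration with validated defaults.

Defaults follow the method's published protocol: 300 K, 1 fs time step,
friction 10/ps, weight terms every 10 fs, free energies and molar-fraction
updates every 0.5 ps, local-averaging window L = 200, and for cycled
explicit-site runs a 10 ps explicit period with 2 ps equilibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


@dataclass
class RunConfig:
    temperature: float = 300.0        # K
    friction: float = 10.0            # 1/ps
    timestep: float = 1.0             # fs
    cutoff: float = 7.5               # Å
    ph: float | None = None           # None => equal-molar mode
    equal_molar: bool = True
    weight_interval: float = 10.0     # fs between weight/Fermi evaluations
    free_energy_interval: float = 500.0   # fs between ΔG evaluations
    fraction_interval: float = 500.0      # fs between fraction updates
    local_window: int = 200           # local-averaging window L
    vmms_k: int | None = None         # explicit sites at a time (None = all)
    site_period: float = 10000.0      # fs each subset stays explicit
    site_equilibration: float = 2000.0  # fs excluded from accumulation
    seed: int = 0
    n_steps: int = 10000
    output_prefix: str = "vmms_run"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.timestep <= 0:
            raise ConfigError("timestep must be positive")
        if self.temperature < 0:
            raise ConfigError("temperature must be non-negative")
        if self.friction < 0:
            raise ConfigError("friction must be non-negative")
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be positive")
        for name in ("weight_interval", "free_energy_interval",
                     "fraction_interval", "site_period",
                     "site_equilibration"):
            value = getattr(self, name)
            if value <= 0:
                raise ConfigError(f"{name} must be positive")
            steps = value / self.timestep
            if abs(steps - round(steps)) > 1e-9:
                raise ConfigError(f"{name} must be a multiple of the timestep")
        if self.local_window < 1:
            raise ConfigError("local_window must be >= 1")
        if self.ph is not None and self.equal_molar:
            raise ConfigError("choose exactly one of pH mode / equal-molar mode")
        if self.ph is None and not self.equal_molar:
            raise ConfigError("choose exactly one of pH mode / equal-molar mode")
        if self.site_equilibration >= self.site_period:
            raise ConfigError("site_equilibration must be below site_period")

    # step-count views of the cadences
    def steps(self, interval_name: str) -> int:
        return int(round(getattr(self, interval_name) / self.timestep))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML config; unset fields take the protocol defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must hold a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    if data.get("ph") is not None:
        data.setdefault("equal_molar", False)
    try:
        return RunConfig(**data)
    except TypeError as exc:  # wrong types surfaced with field context
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
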