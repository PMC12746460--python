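"""Declarative run configuration (YAML) with validation.

Precedence: command-line flags > config file > defaults.  All defaults are
the production values of the method: cutoff 20 cm^-1, 4000 effective modes,
0.5 fs quadrature/propagation step, 30 ps rate-integral horizon, 5 ps of
dynamics with snapshots at 40, 200, 600 and 5000 fs.  The temperature has
no default and must always be given explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """A configuration value failed validation."""


@dataclass(frozen=True)
class RunConfig:
    temperature_K: float
    preset: str | None = None
    hamiltonian_path: str | None = None
    density_files: dict[str, str] | None = None
    omega_star_cm1: float = 20.0
    n_modes: int = 4000
    dt_fs: float = 0.5
    t_max_rate_fs: float = 30000.0
    t_end_dynamics_fs: float = 5000.0
    snapshot_times_fs: tuple[float, ...] = (40.0, 200.0, 600.0, 5000.0)
    initial_site: str | None = None
    n_realizations: int = 1
    seed: int = 0
    sigma_override_cm1: float | None = None
    store_stride: int = 10
    n_workers: int = 1
    output: str | None = None
    lineshape_cache: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "snapshot_times_fs", tuple(float(t) for t in self.snapshot_times_fs))
        errors = []
        if not self.temperature_K > 0:
            errors.append("temperature_K must be strictly positive")
        if self.preset is None and (self.hamiltonian_path is None or not self.density_files):
            errors.append("either a preset or hamiltonian_path plus density_files is required")
        if not self.omega_star_cm1 > 0:
            errors.append("omega_star_cm1 must be strictly positive")
        if self.n_modes < 2:
            errors.append("n_modes must be at least 2")
        for name in ("dt_fs", "t_max_rate_fs", "t_end_dynamics_fs"):
            if not getattr(self, name) > 0:
                errors.append(f"{name} must be strictly positive")
        if any(t <= 0 for t in self.snapshot_times_fs):
            errors.append("snapshot times must be strictly positive")
        if any(t > self.t_end_dynamics_fs for t in self.snapshot_times_fs):
            errors.append("snapshot times must not exceed t_end_dynamics_fs")
        if self.n_realizations < 1:
            errors.append("n_realizations must be at least 1")
        if self.store_stride < 1 or self.n_workers < 1:
            errors.append("store_stride and n_workers must be at least 1")
        if errors:
            raise ConfigError("; ".join(errors))

    def override(self, **kwargs) -> "RunConfig":
        """New config with the given fields replaced (Nones are ignored)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "temperature_K" not in raw:
        raise ConfigError("temperature_K is required (no default)")
    return RunConfig(**raw)
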