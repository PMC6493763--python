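"""Run configuration: structured text config files, seeds and atomic output.

A config file is YAML with at most these top-level keys::

    simulation:   # SimParams fields; omitted fields take the defaults
      n: 10000
      sigma_eps_t: 0.05
    experiment:   # experiment-specific settings
      grid: "0:0.2:0.05"
      mc_replicates: 10
    output_dir: out
    seed: 1
    log_level: INFO

Unknown keys are rejected at any level (anti-typo contract).  One global
seed expands deterministically into per-component random streams via a
CRC32 hash of the component name used as a SeedSequence spawn key, so
adding an experiment never perturbs another experiment's stream.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .exceptions import ConfigError
from .params import SimParams

__all__ = [
    "ExperimentConfig",
    "RunConfig",
    "load_config",
    "dump_config",
    "component_rng",
    "parse_grid",
    "atomic_write_text",
    "write_json",
    "write_csv",
]


def component_rng(seed: int | None, component: str) -> np.random.Generator:
    """Deterministic per-component random stream derived from one global seed."""
    key = zlib.crc32(component.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def parse_grid(spec: str | list | tuple | np.ndarray) -> np.ndarray:
    """Parse a grid: either an explicit list or a "start:stop:step" string.

    The string form includes both endpoints (up to floating-point rounding
    of the step count).
    """
    if isinstance(spec, (list, tuple, np.ndarray)):
        grid = np.asarray(spec, dtype=float).ravel()
        if grid.size == 0:
            raise ConfigError("grid is empty")
        return grid
    parts = str(spec).split(":")
    if len(parts) != 3:
        raise ConfigError(f"grid must be 'start:stop:step', got {spec!r}")
    try:
        start, stop, step = (float(p) for p in parts)
    except ValueError as exc:
        raise ConfigError(f"non-numeric grid component in {spec!r}") from exc
    if step <= 0 or stop < start:
        raise ConfigError(f"grid {spec!r} must have step > 0 and stop >= start")
    count = int(round((stop - start) / step)) + 1
    return start + step * np.arange(count)


@dataclass(frozen=True)
class ExperimentConfig:
    """Experiment-level settings shared by the sweep subcommands."""

    grid: str | None = None
    rho_grid: str | None = None
    mc_replicates: int = 10
    sigma_eps_t_fixed: float = 0.05
    group_size: int = 3

    @classmethod
    def from_dict(cls, mapping: dict[str, Any]) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ConfigError(f"unknown experiment key(s): {', '.join(unknown)}")
        return cls(**mapping)


@dataclass(frozen=True)
class RunConfig:
    simulation: SimParams = field(default_factory=SimParams)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    output_dir: Path = Path("telosim-out")
    seed: int | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulation": self.simulation.to_dict(),
            "experiment": dataclasses.asdict(self.experiment),
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "log_level": self.log_level,
        }


_TOP_LEVEL_KEYS = {"simulation", "experiment", "output_dir", "seed", "log_level"}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys raise :class:`ConfigError` naming the key; omitted
    simulation fields take the package defaults.
    """
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = sorted(set(raw) - _TOP_LEVEL_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    sim_block = raw.get("simulation") or {}
    if not isinstance(sim_block, dict):
        raise ConfigError(f"{path}: 'simulation' must be a mapping")
    try:
        simulation = SimParams.from_dict(sim_block)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    exp_block = raw.get("experiment") or {}
    if not isinstance(exp_block, dict):
        raise ConfigError(f"{path}: 'experiment' must be a mapping")
    experiment = ExperimentConfig.from_dict(exp_block)
    seed = raw.get("seed")
    if seed is not None and not isinstance(seed, int):
        raise ConfigError(f"{path}: seed must be an integer, got {seed!r}")
    return RunConfig(
        simulation=simulation,
        experiment=experiment,
        output_dir=Path(raw.get("output_dir", "telosim-out")),
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
    )


def dump_config(config: RunConfig, path: str | Path) -> None:
    atomic_write_text(path, yaml.safe_dump(config.to_dict(), sort_keys=False))


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text atomically (write to a sibling temp file, then rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def write_json(path: str | Path, payload: Any) -> None:
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_csv(path: str | Path, frame) -> None:
    atomic_write_text(path, frame.to_csv(index=False, float_format="%.17g"))
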