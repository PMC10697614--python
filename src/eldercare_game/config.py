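"""Run configuration: defaults, file loading, validation.

A run configuration names the parameter file (or the bundled baseline),
selects modes and agents, and fixes the grids, tolerances, seed and report
rounding used by the command-line entry points.  Config files are YAML or
JSON mappings whose keys match :class:`RunConfig` field names; unknown
keys are an error and every applied default is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import yaml

from .model import GameParameters

__all__ = ["RunConfig", "baseline_params_path", "load_config", "load_params"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    params_file: str | None = None          # None -> bundled baseline
    modes: tuple[str, ...] = ("N", "H", "G")
    agents: tuple[str, ...] = ("elderly", "government")
    output_dir: str = "results"
    cost_grid: tuple[float, float, int] = (0.0, 10.0, 50)   # start, stop, points
    state_grid: tuple[float, float, int] = (-2.0, 10.0, 13)
    x0: tuple[float, float] = (1.0, 1.0)
    horizon: float = 100.0
    step: float = 0.5
    tolerance: float = 1e-9
    seed: int = 0
    round_decimals: int = 2

    def __post_init__(self) -> None:
        if self.tolerance <= 0.0:
            raise ValueError(f"tolerance must be positive, got {self.tolerance}")
        for name in ("cost_grid", "state_grid"):
            grid = getattr(self, name)
            if len(grid) != 3 or int(grid[2]) < 1:
                raise ValueError(f"{name} must be (start, stop, points>=1), got {grid}")
        if self.horizon <= 0.0 or self.step <= 0.0:
            raise ValueError("horizon and step must be positive")
        unknown_modes = set(self.modes) - {"N", "H", "G"}
        if unknown_modes:
            raise ValueError(f"unknown modes: {sorted(unknown_modes)}")
        unknown_agents = set(self.agents) - {"elderly", "government"}
        if unknown_agents:
            raise ValueError(f"unknown agents: {sorted(unknown_agents)}")
        if self.params_file is not None and not Path(self.params_file).exists():
            raise ValueError(f"parameter file does not exist: {self.params_file}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["modes"] = list(self.modes)
        d["agents"] = list(self.agents)
        d["cost_grid"] = list(self.cost_grid)
        d["state_grid"] = list(self.state_grid)
        d["x0"] = list(self.x0)
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration, applying and logging defaults."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"{path}: could not parse config: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    for name in known - set(data):
        default = getattr(RunConfig, name, None)
        logger.info("config %s: using default %s = %r", path, name, default)
    for name in ("modes", "agents", "cost_grid", "state_grid", "x0"):
        if name in data and isinstance(data[name], list):
            data[name] = tuple(data[name])
    return RunConfig(**data)


def baseline_params_path() -> Path:
    """Path to the bundled baseline parameter file."""
    return Path(str(resources.files("eldercare_game").joinpath("data/baseline.yaml")))


def load_params(config: RunConfig) -> GameParameters:
    """Load the configured parameter file, falling back to the baseline."""
    if config.params_file is None:
        logger.info("no parameter file configured; using bundled baseline")
        return GameParameters.from_file(baseline_params_path())
    return GameParameters.from_file(config.params_file)
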