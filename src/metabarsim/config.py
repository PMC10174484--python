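"""Run configuration: a YAML key-value file mirroring the grid and protocol.

Every field has a documented default equal to the main-text simulation
setting, so an empty config runs the standard design.  Example::

    grid:
      richness_levels: [50]
      lambda_levels: 18          # count -> log-spaced 0.5..10000, or a list
      gamma_levels: [5]
      n_realizations: 2000
    protocol:
      volume_uL: 1.0
      n_pcr1: 35
      n_pcr2: 10
      cleanup_fraction: 0.20
      index_efficiency: 0.9
      min_reads: 60000
      max_reads: 140000
    seed: 1
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import yaml

from .core import ProtocolParams, ReadDepthRule
from .errors import InvalidParameterError
from .scenarios import ScenarioGrid, build_scenario_grid, default_lambda_levels

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    grid: ScenarioGrid
    protocol: ProtocolParams
    seed: int
    redraw_efficiencies: bool = True
    config_hash: str = ""


def _protocol_from_mapping(mapping: dict) -> ProtocolParams:
    mapping = dict(mapping)
    depth = ReadDepthRule(int(mapping.pop("min_reads", 60_000)),
                          int(mapping.pop("max_reads", 140_000)))
    known = {"volume_uL", "n_pcr1", "n_pcr2", "cleanup_fraction", "index_efficiency"}
    unknown = set(mapping) - known
    if unknown:
        raise InvalidParameterError(f"unknown protocol keys: {sorted(unknown)}")
    return ProtocolParams(depth_rule=depth, **mapping)


def _grid_from_mapping(mapping: dict, seed: int) -> tuple[ScenarioGrid, bool]:
    mapping = dict(mapping)
    lam = mapping.pop("lambda_levels", None)
    if isinstance(lam, int):
        lam = default_lambda_levels(lam)
    elif lam is not None:
        lam = np.asarray(lam, dtype=float)
    redraw = bool(mapping.pop("redraw_efficiencies", True))
    known = {"richness_levels", "gamma_levels", "n_realizations", "abundance_profile"}
    unknown = set(mapping) - known
    if unknown:
        raise InvalidParameterError(f"unknown grid keys: {sorted(unknown)}")
    grid = build_scenario_grid(lambda_levels=lam, master_seed=seed, **mapping)
    return grid, redraw


def load_config(path, seed_override: int | None = None) -> RunConfig:
    """Parse and validate a YAML run config; raises InvalidParameterError on
    any malformed field before any simulation work starts."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise InvalidParameterError("config root must be a mapping")
    unknown = set(data) - {"grid", "protocol", "seed"}
    if unknown:
        raise InvalidParameterError(f"unknown config sections: {sorted(unknown)}")
    seed = int(seed_override if seed_override is not None else data.get("seed", 0))
    try:
        grid, redraw = _grid_from_mapping(data.get("grid", {}) or {}, seed)
        protocol = _protocol_from_mapping(data.get("protocol", {}) or {})
    except TypeError as exc:  # unexpected keyword / wrong type from YAML
        raise InvalidParameterError(str(exc)) from exc
    digest = hashlib.sha256(raw.encode("utf-8")).hexdigest()[:16]
    return RunConfig(grid=grid, protocol=protocol, seed=seed,
                     redraw_efficiencies=redraw, config_hash=digest)
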