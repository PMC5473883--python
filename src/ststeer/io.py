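"""File-level I/O: assemblage JSON, scenario configuration files (YAML/JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .assemblage import Assemblage, Scenario
from .fixtures import discard_channel_scenario, werner_scenario
from .models import fmo_scenario, three_qubit_chain_scenario

__all__ = [
    "load_assemblage",
    "save_assemblage",
    "load_scenario_config",
    "scenario_from_config",
    "save_result",
]


def load_assemblage(path) -> Assemblage:
    with open(path) as fh:
        return Assemblage.from_json(json.load(fh))


def save_assemblage(assemblage: Assemblage, path) -> None:
    with open(path, "w") as fh:
        json.dump(assemblage.to_json(), fh, indent=2)


def load_scenario_config(path) -> dict:
    """Read a scenario configuration file (YAML or JSON by extension)."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def scenario_from_config(config: dict) -> tuple[Scenario, np.ndarray, str]:
    """Build (scenario, time_grid, measure) from a configuration mapping.

    Schema: ``{model: chain|fmo|werner|discard, parameters: {...},
    target_site: ..., time_grid: {start, stop, steps}, measure: weight|robustness}``.
    The measurement set is the Pauli set in every shipped model.
    """
    kind = config.get("model")
    params = dict(config.get("parameters", {}))
    if kind == "chain":
        scenario = three_qubit_chain_scenario(
            J12=params.get("J12", 1.0),
            J23=params.get("J23", 1.0),
            gamma=params.get("gamma", 0.0),
            target=config.get("target_site", 3),
        )
    elif kind == "fmo":
        scenario = fmo_scenario(
            target_site=config.get("target_site", 5),
            T=params.get("temperature", 15.0),
            sink_rate=params.get("sink_rate", 5.3),
        )
    elif kind == "werner":
        scenario = werner_scenario(params.get("p", 1.0))
    elif kind == "discard":
        scenario = discard_channel_scenario()
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    tg = config.get("time_grid", {"start": 0.0, "stop": 1.0, "steps": 11})
    grid = np.linspace(float(tg.get("start", 0.0)), float(tg["stop"]), int(tg["steps"]))
    measure = config.get("measure", "weight")
    return scenario, grid, measure


def save_result(result, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_json(), fh, indent=2)
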