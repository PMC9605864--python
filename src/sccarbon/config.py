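"""YAML (de)serialization for generator and run configurations, with every
anchor and seed explicit."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .climate import PulseSpec
from .scenarios import GeneratorConfig, QuantileAnchor
from .valuation import RunConfig


def _plain(value):
    if isinstance(value, QuantileAnchor):
        return [value.q05, value.q50, value.q95]
    if isinstance(value, PulseSpec):
        return {"year": value.year, "mass_mtc": value.mass_mtc}
    if isinstance(value, tuple):
        return list(value)
    return value


def generator_config_to_yaml(config: GeneratorConfig, path) -> None:
    data = {
        f.name: _plain(getattr(config, f.name))
        for f in dataclasses.fields(config)
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def generator_config_from_yaml(path) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("pop_2300", "growth", "co2_2100"):
        if key in data:
            data[key] = QuantileAnchor(*data[key])
    for key in ("ch4_anchor_path", "n2o_anchor_path"):
        if key in data:
            data[key] = tuple(tuple(p) for p in data[key])
    config = GeneratorConfig(**data)
    config.validate()
    return config


_RUN_SCALARS = (
    "mode", "n_draws", "master_seed", "near_term_rate", "sectors",
    "n_countries", "n_segments", "n_climate_ensemble", "consumption_basis",
    "consumption_floor", "ag_theta_fixed", "store_paths",
)


def run_config_to_yaml(config: RunConfig, path) -> None:
    data = {name: _plain(getattr(config, name)) for name in _RUN_SCALARS}
    data["pulse"] = _plain(config.pulse)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def run_config_from_yaml(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "pulse" in data:
        data["pulse"] = PulseSpec(**data["pulse"])
    if "sectors" in data:
        data["sectors"] = tuple(data["sectors"])
    config = RunConfig(**data)
    config.validate()
    return config
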