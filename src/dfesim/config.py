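"""YAML/dict config loading for simulation runs and scenario grids."""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiments import Scenario, out_of_africa_demography
from .models import DemographyModel, SelectionModel, SimConfig

__all__ = [
    "selection_model_from_dict",
    "sim_config_from_dict",
    "scenarios_from_config",
    "load_yaml",
]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def selection_model_from_dict(d: dict | str | None) -> SelectionModel:
    if d is None or d == "neutral":
        return SelectionModel("neutral")
    if isinstance(d, str):
        raise ValueError(f"unknown selection model shorthand {d!r}")
    return SelectionModel(
        kind=d["kind"],
        s=d.get("s", 0.0),
        selected_fraction=d.get("selected_fraction", 1.0),
        gamma_shape=d.get("gamma_shape"),
        gamma_scale_2Ns=d.get("gamma_scale_2Ns"),
        h=d.get("h", 0.5),
    )


def _demography_from(d) -> DemographyModel | None:
    if d is None:
        return None
    if d == "out_of_africa":
        return out_of_africa_demography()
    return DemographyModel(
        demes=tuple((name, tuple(map(tuple, epochs))) for name, epochs in d["demes"]),
        splits=tuple(map(tuple, d.get("splits", ()))),
        migration=tuple(
            (t, tuple(map(tuple, mat))) for t, mat in d.get("migration", ())
        ),
    )


def sim_config_from_dict(d: dict) -> SimConfig:
    kw = dict(d)
    if "syn_model" in kw:
        kw["syn_model"] = selection_model_from_dict(kw["syn_model"])
    if "ns_model" in kw:
        kw["ns_model"] = selection_model_from_dict(kw["ns_model"])
    if "demography" in kw:
        kw["demography"] = _demography_from(kw["demography"])
    return SimConfig(**kw)


def scenarios_from_config(cfg: dict) -> list[Scenario]:
    """Build the scenario list of a pipeline config.

    Top-level keys: ``defaults`` (Scenario/Sim shared knobs) and
    ``scenarios`` (list of per-scenario dicts with at least ``name`` and
    ``syn_model``)."""
    defaults = cfg.get("defaults", {})
    out = []
    for sd in cfg["scenarios"]:
        merged = {**defaults, **sd}
        sim_overrides = {
            **defaults.get("sim_overrides", {}),
            **sd.get("sim_overrides", {}),
        }
        out.append(
            Scenario(
                name=merged["name"],
                syn_model=selection_model_from_dict(merged.get("syn_model")),
                r=merged.get("r", 1e-8),
                demography=_demography_from(merged.get("demography")),
                n_replicates=merged.get("n_replicates", 20),
                n_chunks=merged.get("n_chunks", 22),
                rescale_Q=merged.get("rescale_Q", 1),
                seed=merged.get("seed", 0),
                sim_overrides=sim_overrides,
            )
        )
    return out
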