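"""Structured configuration (YAML) for scenarios, physiology and simulation."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .exposure import ChemicalParams, ExposureScenario
from .life_history import GrowthModel, ReproductionSchedule
from .ppk_dynamic import DEFAULT_STEP, SimulationFeatures
from .ppk_static import StaticBody
from .synthetic_data import NoiseModel


@dataclass
class Config:
    growth: GrowthModel
    schedule: ReproductionSchedule
    chemical: ChemicalParams
    scenario: ExposureScenario
    body: StaticBody
    features: SimulationFeatures
    noise: NoiseModel
    target_age: float
    sampling_years: np.ndarray
    step: float


def _sampling_years(block: dict) -> np.ndarray:
    if "sampling_years" in block:
        return np.asarray(block["sampling_years"], dtype=float)
    return np.arange(
        float(block["start"]), float(block["stop"]) + 1e-9, float(block.get("every", 1.0))
    )


def load_config(path=None) -> Config:
    """Load a YAML config; omitted blocks fall back to packaged defaults."""
    defaults = yaml.safe_load(
        resources.files("cstdkit").joinpath("data/default_config.yaml").read_text()
    )
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = {**defaults, **user}
    for key in defaults:
        if isinstance(defaults[key], dict) and key in user:
            cfg[key] = {**defaults[key], **(user[key] or {})}
    g = cfg["growth"]
    sim = cfg["simulation"]
    return Config(
        growth=GrowthModel(
            tuple(g["anchor_ages"]),
            tuple(g["body_weight_kg"]),
            tuple(g["lipid_fraction"]),
        ),
        schedule=ReproductionSchedule(**cfg["schedule"]),
        chemical=ChemicalParams(**cfg["chemical"]),
        scenario=ExposureScenario(**cfg["scenario"]),
        body=StaticBody(**cfg["body"]),
        features=SimulationFeatures(**cfg["features"]),
        noise=NoiseModel(**cfg["noise"]),
        target_age=float(sim["target_age"]),
        sampling_years=_sampling_years(sim),
        step=float(sim.get("step", DEFAULT_STEP)),
    )
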