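"""Run configuration: defaults plus YAML overlay.

The YAML layout mirrors the engine's parameter groups::

    mode: testing            # training allows resets; testing does not
    timestep_ms: 1.0
    seed: 0
    mesh: null               # optional OBJ/STL path replacing the toe fixture
    deformation: {stiffness: 2.0, damping: 6.0, ...}
    needle: {b: 0.2, k1: 0.6, k2: 7.9, c: 0.15, depth_limit_mm: 30.0}
    springs: {elevation_k: 2.0, grasp_k: 1.5, pierce_threshold_n: 1.815}
    contact: {syringe: {stiffness: 0.2, ...}, ...}
    criteria: {angle_min_deg: 70.0, depth_fraction: 0.8, min_cuts: 3, ...}
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .deformation import DeformationParams
from .forces import DEFAULT_TOOL_PROPERTIES, SurfaceProperties
from .tasks import TaskCriteria

__all__ = ["RunConfig", "load_config"]

TESTING_BLOCK_SIZE = 10  # attempts per task in testing mode


@dataclass
class RunConfig:
    mode: str = "testing"
    timestep_ms: float = 1.0
    seed: int = 0
    mesh: str | None = None
    output_dir: str = "."
    deformation: DeformationParams = field(default_factory=DeformationParams)
    criteria: TaskCriteria = field(default_factory=TaskCriteria)
    contact: dict = field(default_factory=lambda: dict(DEFAULT_TOOL_PROPERTIES))
    needle: dict = field(
        default_factory=lambda: {
            "b": 0.2,
            "k1": 0.6,
            "k2": 7.9,
            "c": 0.15,
            "depth_limit_mm": 30.0,
        }
    )
    springs: dict = field(
        default_factory=lambda: {
            "elevation_k": 2.0,
            "grasp_k": 1.5,
            "pierce_threshold_n": 1.815,
        }
    )

    def __post_init__(self) -> None:
        if self.mode not in ("training", "testing"):
            raise ValueError("mode must be 'training' or 'testing'")

    @property
    def allows_retries(self) -> bool:
        return self.mode == "training"


def _merged(dc, overrides: dict):
    valid = {f.name for f in dataclasses.fields(dc)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} for {type(dc).__name__}")
    return dataclasses.replace(dc, **overrides)


def load_config(path=None) -> RunConfig:
    """Defaults, overridden by the YAML file when given."""
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    for key in ("mode", "timestep_ms", "seed", "mesh", "output_dir"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "deformation" in raw:
        cfg.deformation = _merged(cfg.deformation, raw["deformation"])
    if "criteria" in raw:
        crit = dict(raw["criteria"])
        for key in ("blade_half_extents",):
            if key in crit:
                crit[key] = tuple(crit[key])
        cfg.criteria = _merged(cfg.criteria, crit)
    if "needle" in raw:
        cfg.needle = {**cfg.needle, **raw["needle"]}
    if "springs" in raw:
        cfg.springs = {**cfg.springs, **raw["springs"]}
    if "contact" in raw:
        for tool, props in raw["contact"].items():
            base = cfg.contact.get(tool)
            merged = {**(dataclasses.asdict(base) if base else {}), **props}
            cfg.contact[tool] = SurfaceProperties(**merged)
    if cfg.mode not in ("training", "testing"):
        raise ValueError("mode must be 'training' or 'testing'")
    return cfg
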