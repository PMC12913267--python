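"""Named model configurations and flat YAML config IO.

The ``*-aggregate`` presets are the final models for the group-average
data of each task; the remaining presets are the cluster models fit to
subgroups of participants with similar speed/accuracy profiles.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Any, Mapping

import yaml

from .display import COLOR, ORIENTATION, SHAPE, make_task_spec
from .engine import ModelConfig, TimingParams
from .motor import ManualParams, OculomotorParams
from .strategy import StrategyConfig
from .vision import AvailabilityParams, CrowdingParams


def _shape(theta: float, phi: float, slip: float, **strategy: Any) -> dict:
    return {
        "task": "shape",
        "availability": {"theta": {SHAPE: theta}},
        "crowding": {"phi": {SHAPE: phi}},
        "manual": {"slip_er": slip},
        "strategy": {"variant": "basic", **strategy},
    }


def _color(theta: float, phi: float, slip: float) -> dict:
    return {
        "task": "color",
        "availability": {"theta": {COLOR: theta, ORIENTATION: theta}},
        "crowding": {"phi": {COLOR: phi, ORIENTATION: phi}},
        "manual": {"slip_er": slip},
        "strategy": {"variant": "fixed_eye"},
    }


def _conjunction(theta_c: float, phi_c: float, theta_o: float, phi_o: float,
                 slip: float, n_max: int | None) -> dict:
    strategy: dict[str, Any] = {
        "variant": "basic",
        "confirm_positive": True,
        "confirm_negative": True,
    }
    if n_max is not None:
        strategy["limited_fixations"] = n_max
    return {
        "task": "conjunction",
        "availability": {"theta": {COLOR: theta_c, ORIENTATION: theta_o}},
        "crowding": {"phi": {COLOR: phi_c, ORIENTATION: phi_o}},
        "manual": {"slip_er": slip},
        "strategy": strategy,
    }


#: Final aggregate-data models plus the participant-cluster models.
PRESETS: dict[str, dict] = {
    # Aggregate-data models
    "shape-aggregate": _shape(0.425, 0.075, 0.014),
    "color-aggregate": _color(0.11, 0.0, 0.014),
    "conjunction-aggregate": _conjunction(0.11, 0.025, 0.20, 0.025, 0.014, 3),
    # Shape-task clusters
    "shape-slow-lowER": _shape(0.375, 0.025, 0.01),
    "shape-veryslow-medER": _shape(0.6, 0.05, 0.005),
    "shape-negacc-highER": _shape(0.435, 0.150, 0.023),
    # Color-task clusters (phi is a placeholder; fixed-eye makes it inert)
    "color-slow-lowER": _color(0.09, 0.025, 0.006),
    "color-fast-medER": _color(0.10, 0.025, 0.009),
    "color-fast-highER": _color(0.115, 0.025, 0.021),
    # Conjunction-task clusters
    "conjunction-sloped-lowER": _conjunction(0.15, 0.025, 0.25, 0.05, 0.0015, None),
    "conjunction-almostflat-medER": _conjunction(0.10, 0.075, 0.15, 0.075, 0.0045, 3),
    "conjunction-almostflat-highER": _conjunction(0.11, 0.025, 0.18, 0.025, 0.032, 2),
}


def config_from_dict(doc: Mapping[str, Any]) -> ModelConfig:
    """Build a :class:`ModelConfig` from a flat configuration mapping."""
    spec = make_task_spec(doc["task"])
    avail = AvailabilityParams(
        theta=dict(doc["availability"]["theta"]),
        sigma=float(doc.get("availability", {}).get("sigma", 0.5)),
    )
    crowd = CrowdingParams(phi=dict(doc.get("crowding", {}).get("phi", {})))
    oculo = OculomotorParams(**doc.get("oculomotor", {}))
    manual = ManualParams(**doc.get("manual", {}))
    strategy = StrategyConfig(**doc.get("strategy", {}))
    timing = TimingParams(**doc.get("timing", {}))
    return ModelConfig(
        task=spec, avail=avail, crowd=crowd, oculo=oculo,
        manual=manual, strategy=strategy, timing=timing,
    )


def config_to_dict(config: ModelConfig) -> dict:
    return {
        "task": config.task.name,
        "availability": {"theta": dict(config.avail.theta), "sigma": config.avail.sigma},
        "crowding": {"phi": dict(config.crowd.phi)},
        "oculomotor": asdict(config.oculo),
        "manual": asdict(config.manual),
        "strategy": asdict(config.strategy),
        "timing": asdict(config.timing),
    }


def get_preset(name: str) -> ModelConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return config_from_dict(PRESETS[name])


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
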