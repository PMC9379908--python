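"""YAML (de)serialization of the nested model and study configurations.

Every parameter group is a frozen dataclass; configs round-trip through
plain nested dictionaries so a study's exact parameterization can be
archived alongside its outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from splitfert.column import (
    GridConfig,
    InitialPools,
    ModelConfig,
    ReactionParams,
    TransportParams,
    UptakeParams,
)
from splitfert.hydraulics import SoilHydraulics
from splitfert.optimize import StabilityConfig, TimingGrid
from splitfert.precip import SpiConfig
from splitfert.roots import RootParams

_MODEL_GROUPS = {
    "hydraulics": SoilHydraulics,
    "transport": TransportParams,
    "reactions": ReactionParams,
    "roots": RootParams,
    "uptake": UptakeParams,
    "pools": InitialPools,
    "grid": GridConfig,
}


def model_config_to_dict(cfg: ModelConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name in _MODEL_GROUPS:
        out[name] = dataclasses.asdict(getattr(cfg, name))
    out["evaporation_mm_d"] = cfg.evaporation_mm_d
    return out


def model_config_from_dict(d: dict[str, Any]) -> ModelConfig:
    kwargs: dict[str, Any] = {}
    for name, cls in _MODEL_GROUPS.items():
        if name in d:
            kwargs[name] = cls(**d[name])
    if "evaporation_mm_d" in d:
        kwargs["evaporation_mm_d"] = float(d["evaporation_mm_d"])
    return ModelConfig(**kwargs)


def dump_model_config(cfg: ModelConfig) -> str:
    return yaml.safe_dump(model_config_to_dict(cfg), sort_keys=False)


def load_model_config(path: str | Path) -> ModelConfig:
    return model_config_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def study_config_to_dict(cfg: "StudyConfig") -> dict[str, Any]:
    from splitfert.study import StudyConfig  # local import to avoid a cycle

    return {
        "grid": dataclasses.asdict(cfg.grid),
        "model": model_config_to_dict(cfg.model),
        "stability": dataclasses.asdict(cfg.stability),
        "close_tol": cfg.close_tol,
        "spi": {
            "aggregation_months": cfg.spi.aggregation_months,
            "fit_years": list(cfg.spi.fit_years) if cfg.spi.fit_years else None,
            "zero_inflated": cfg.spi.zero_inflated,
            "min_fit_years": cfg.spi.min_fit_years,
        },
        "ref_years": list(cfg.ref_years) if cfg.ref_years else None,
        "rolling_width": cfg.rolling_width,
        "years": list(cfg.years) if cfg.years else None,
    }


def study_config_from_dict(d: dict[str, Any]) -> "StudyConfig":
    from splitfert.study import StudyConfig

    kwargs: dict[str, Any] = {}
    if "grid" in d:
        kwargs["grid"] = TimingGrid(**d["grid"])
    if "model" in d:
        kwargs["model"] = model_config_from_dict(d["model"])
    if "stability" in d:
        kwargs["stability"] = StabilityConfig(**d["stability"])
    if "close_tol" in d:
        kwargs["close_tol"] = float(d["close_tol"])
    if "spi" in d:
        s = dict(d["spi"])
        if s.get("fit_years"):
            s["fit_years"] = tuple(s["fit_years"])
        kwargs["spi"] = SpiConfig(**s)
    if d.get("ref_years"):
        kwargs["ref_years"] = tuple(d["ref_years"])
    if "rolling_width" in d:
        kwargs["rolling_width"] = int(d["rolling_width"])
    if d.get("years"):
        kwargs["years"] = tuple(d["years"])
    return StudyConfig(**kwargs)


def dump_study_config(cfg: "StudyConfig", path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(study_config_to_dict(cfg), sort_keys=False))


def load_study_config(path: str | Path) -> "StudyConfig":
    return study_config_from_dict(yaml.safe_load(Path(path).read_text()) or {})
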