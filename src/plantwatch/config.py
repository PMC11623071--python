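"""Run configuration: one YAML document covering engine, pipeline, thresholds.

A run's effective configuration is echoed into its output directory so every
command is reproducible from the echoed file plus the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fuzzy import ELSLEngine, default_engine, engine_from_dict, engine_to_dict
from .imaging import CropRect
from .pipeline import PipelineConfig
from .sensors import Thresholds

__all__ = ["RunConfig", "default_run_config", "load_run_config", "save_run_config"]


@dataclass(frozen=True)
class RunConfig:
    engine: ELSLEngine
    pipeline: PipelineConfig
    thresholds: Thresholds
    seed: int = 0

    def to_dict(self) -> dict:
        p = self.pipeline
        return {
            "seed": self.seed,
            "engine": engine_to_dict(self.engine),
            "pipeline": {
                "crop": (
                    None
                    if p.crop is None
                    else [p.crop.x1, p.crop.y1, p.crop.width, p.crop.height]
                ),
                "blur_size": p.blur_size,
                "blur_sigma": p.blur_sigma,
                "edge_method": p.edge_method,
                "edge_low": p.edge_low,
                "edge_high": p.edge_high,
                "min_spot_area": p.min_spot_area,
                "area_clamp": p.area_clamp,
                "decision_boundary": p.decision_boundary,
            },
            "thresholds": {
                "moisture_max_pct": self.thresholds.moisture_max_pct,
                "co2_min_ppm": self.thresholds.co2_min_ppm,
                "temp_low_c": self.thresholds.temp_low_c,
                "temp_high_c": self.thresholds.temp_high_c,
            },
        }


def default_run_config(seed: int = 0) -> RunConfig:
    return RunConfig(
        engine=default_engine(),
        pipeline=PipelineConfig(),
        thresholds=Thresholds(),
        seed=seed,
    )


def _config_from_dict(d: dict) -> RunConfig:
    base = default_run_config()
    engine = engine_from_dict(d["engine"]) if "engine" in d else base.engine
    pd_ = d.get("pipeline", {})
    crop = pd_.get("crop")
    pipeline = PipelineConfig(
        crop=None if crop is None else CropRect(*(int(v) for v in crop)),
        blur_size=int(pd_.get("blur_size", 5)),
        blur_sigma=float(pd_.get("blur_sigma", 8.0)),
        edge_method=str(pd_.get("edge_method", "canny")),
        edge_low=pd_.get("edge_low"),
        edge_high=pd_.get("edge_high"),
        min_spot_area=int(pd_.get("min_spot_area", 5)),
        area_clamp=float(pd_.get("area_clamp", 12000.0)),
        decision_boundary=float(pd_.get("decision_boundary", 50.0)),
    )
    td = d.get("thresholds", {})
    thresholds = Thresholds(
        moisture_max_pct=float(td.get("moisture_max_pct", 20.0)),
        co2_min_ppm=float(td.get("co2_min_ppm", 50.0)),
        temp_low_c=float(td.get("temp_low_c", 12.0)),
        temp_high_c=float(td.get("temp_high_c", 15.0)),
    )
    return RunConfig(
        engine=engine,
        pipeline=pipeline,
        thresholds=thresholds,
        seed=int(d.get("seed", 0)),
    )


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return _config_from_dict(d)


def save_run_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
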