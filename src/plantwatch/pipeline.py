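"""End-to-end leaf-spot pipeline: frame in, per-spot decisions out.

Ties the image operations to the fuzzy engine: segment candidate spots,
compute the (intensity difference, area) features, classify each spot as
Defect or Noise, annotate defects with red circles, and reduce the frame to
a binary pest call (pests present iff at least one Defect).  Also houses the
trial-agreement evaluation used for the bundled twenty-trial benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fuzzy import ELSLEngine, InferenceResult, default_engine
from .imaging import (
    CropRect,
    SpotFeatures,
    SpotRegion,
    annotate,
    compute_features,
    crop_frame,
    detect_edges,
    extract_spots,
    fill_holes,
    gaussian_blur,
    invert,
    to_grayscale,
)
from .reference import TrialRecord

__all__ = [
    "PipelineConfig",
    "SpotDecision",
    "FrameResult",
    "classify_spots",
    "process_frame",
    "frame_pest_call",
    "evaluate_trials",
    "decisions_to_dataframe",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters with the shipped defaults."""

    crop: CropRect | None = None  # None = analyze the full frame
    blur_size: int = 5
    blur_sigma: float = 8.0
    edge_method: str = "canny"
    edge_low: float | None = None  # None = automatic from gradient histogram
    edge_high: float | None = None
    min_spot_area: int = 5
    area_clamp: float = 12000.0  # top of the Area universe
    decision_boundary: float = 50.0


@dataclass(frozen=True)
class SpotDecision:
    spot: SpotRegion
    features: SpotFeatures
    inference: InferenceResult
    area_clamped: bool = False

    @property
    def label(self) -> str:
        return self.inference.label

    @property
    def is_defect(self) -> bool:
        return self.label == "Defect"


@dataclass
class FrameResult:
    frame_id: str
    gray: np.ndarray  # cropped grayscale original
    processed: np.ndarray  # post-inversion binary frame
    decisions: list[SpotDecision] = field(default_factory=list)
    annotated: np.ndarray | None = None

    @property
    def pest_call(self) -> int:
        return frame_pest_call(self.decisions)


def classify_spots(
    features: Sequence[SpotFeatures],
    engine: ELSLEngine | None = None,
    spots: Sequence[SpotRegion] | None = None,
    area_clamp: float = 12000.0,
) -> list[SpotDecision]:
    """Run the fuzzy engine on each spot's features.

    Areas above the Area universe top are clamped to it before inference
    (the engine's memberships are undefined outside the universe; a giant
    dark region is treated like the top of the range) and flagged.
    """
    engine = engine or default_engine()
    if spots is not None and len(spots) != len(features):
        raise ValueError("spots and features must align")
    decisions = []
    for i, f in enumerate(features):
        clamped = f.area > area_clamp
        crisp = {
            "Intensity": f.intensity_diff,
            "Area": min(float(f.area), area_clamp),
        }
        result = engine.infer(crisp)
        decisions.append(
            SpotDecision(
                spot=spots[i] if spots is not None else None,
                features=f,
                inference=result,
                area_clamped=clamped,
            )
        )
    return decisions


def process_frame(
    frame: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    engine: ELSLEngine | None = None,
    frame_id: str = "frame",
) -> FrameResult:
    """Full chain on one frame: crop, segment, classify, annotate."""
    engine = engine or default_engine()
    if engine.decision_boundary != config.decision_boundary:
        engine = ELSLEngine(
            input_sets=engine.input_sets,
            rulebase=engine.rulebase,
            decision_boundary=config.decision_boundary,
        )
    work = crop_frame(frame, config.crop) if config.crop is not None else frame
    gray = to_grayscale(work)
    blurred = gaussian_blur(gray, config.blur_size, config.blur_sigma)
    edges = detect_edges(
        blurred,
        method=config.edge_method,
        low_threshold=config.edge_low,
        high_threshold=config.edge_high,
    )
    processed = invert(fill_holes(edges))
    spots = extract_spots(processed, gray, min_area=config.min_spot_area)
    features = [compute_features(s, gray) for s in spots]
    decisions = classify_spots(
        features, engine=engine, spots=spots, area_clamp=config.area_clamp
    )
    annotated = annotate(work, spots, [d.is_defect for d in decisions])
    return FrameResult(
        frame_id=frame_id,
        gray=gray,
        processed=processed,
        decisions=decisions,
        annotated=annotated,
    )


def frame_pest_call(decisions: Sequence[SpotDecision]) -> int:
    """1 iff at least one spot was classified Defect, else 0."""
    return int(any(d.is_defect for d in decisions))


def evaluate_trials(trials: Sequence[TrialRecord]) -> float:
    """Percent of trials where the detected call matches the real state."""
    trials = list(trials)
    if not trials:
        raise ValueError("cannot evaluate an empty trial list")
    agree = sum(1 for t in trials if t.real_pest == t.detected_pest)
    return 100.0 * agree / len(trials)


def decisions_to_dataframe(
    results: Sequence[FrameResult],
) -> pd.DataFrame:
    """Per-spot decision table (frame_id, spot_id, features, z, label)."""
    rows = []
    for fr in results:
        for d in fr.decisions:
            rows.append(
                {
                    "frame_id": fr.frame_id,
                    "spot_id": d.spot.label if d.spot is not None else -1,
                    "area_px": d.features.area,
                    "intensity_diff": d.features.intensity_diff,
                    "z": d.inference.z,
                    "label": d.label,
                    "area_clamped": d.area_clamped,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame_id",
            "spot_id",
            "area_px",
            "intensity_diff",
            "z",
            "label",
            "area_clamped",
        ],
    )
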