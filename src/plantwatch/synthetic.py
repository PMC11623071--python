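"""Seeded synthetic leaf scenes and sensor streams with ground truth.

The scene generator emulates a top-down photo of a single leaf: a bright
leaf ellipse on a darker background, an optional linear illumination
gradient and shadow polygon, and two populations of planted circular spots —
high-contrast "defect" blobs (pest damage) and low-contrast or tiny "noise"
blobs.  Every planted spot comes back in a ground-truth table with its true
label, so the whole detection pipeline is testable without hardware.

The stream generator emulates a cheap greenhouse sensor: base level plus
drift plus Gaussian jitter, with random dropouts (missing samples) and
out-of-physical-range outliers.

Everything is reproducible bit-for-bit from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .imaging import CropRect
from .reference import BENCHMARK_REAL
from .sensors import SensorReading

__all__ = [
    "SpotSpec",
    "SceneSpec",
    "StreamSpec",
    "SceneRecord",
    "ScenarioBundle",
    "make_leaf_scene",
    "make_sensor_stream",
    "scenario_suite",
    "scene_crop",
    "write_bundle",
    "SCENARIO_NAMES",
]

# color tint with exact unit luminance under the 0.2989/0.5870/0.1140 weights
_TINT_R, _TINT_B = 0.8, 0.6
_TINT_G = (1.0 - 0.2989 * _TINT_R - 0.1140 * _TINT_B) / 0.5870


@dataclass(frozen=True)
class SpotSpec:
    """One planted circular spot: center (row, col), radius px, pixel value."""

    row: float
    col: float
    radius: float
    intensity: float  # planted pixel value, 0-255

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("spot radius must be positive")
        if not 0 <= self.intensity <= 255:
            raise ValueError("spot intensity outside [0, 255]")


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int] = (480, 640)
    leaf_center: tuple[float, float] = (240.0, 320.0)
    leaf_axes: tuple[float, float] = (190.0, 270.0)  # semi-axes (rows, cols)
    leaf_intensity: float = 210.0
    background_intensity: float = 60.0
    gradient_amplitude: float = 0.0  # +- pixel value across the columns
    shadow_polygon: tuple[tuple[float, float], ...] | None = None
    shadow_opacity: float = 0.0
    defects: tuple[SpotSpec, ...] = ()
    noise: tuple[SpotSpec, ...] = ()
    pixel_noise_sigma: float = 1.5
    seed: int = 0

    def contrast(self, spot: SpotSpec) -> float:
        """Planted intensity contrast vs the leaf base, as a 0-1 ratio."""
        return abs(self.leaf_intensity - spot.intensity) / 255.0


@dataclass(frozen=True)
class StreamSpec:
    channel: str
    duration_s: float = 60.0
    dt_s: float = 1.0
    base: float = 40.0
    drift_per_s: float = 0.0
    jitter_sigma: float = 0.0
    dropout_prob: float = 0.0
    outlier_prob: float = 0.0
    outlier_magnitude: float = 200.0  # added to base; chosen out of range
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.outlier_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _disk_mask(row: float, col: float, radius: float, shape):
    """Pixel centers within ``radius`` (inclusive) of the spot center.

    The inclusive convention keeps the rasterized count within ~2 % of
    pi r^2 down to radius 10.
    """
    h, w = shape
    r0, r1 = max(0, int(row - radius) - 1), min(h, int(row + radius) + 2)
    c0, c1 = max(0, int(col - radius) - 1), min(w, int(col + radius) + 2)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    return rr[mask], cc[mask]


def _inside_leaf(spec: SceneSpec, row: float, col: float) -> bool:
    cr, cc = spec.leaf_center
    ar, ac = spec.leaf_axes
    return ((row - cr) / ar) ** 2 + ((col - cc) / ac) ** 2 <= 1.0


def scene_crop(spec: SceneSpec, margin: int = 6) -> CropRect:
    """The rectangle inscribed in the leaf ellipse (the analysis region).

    Cropping inside the leaf keeps the leaf outline itself out of the edge
    map, so filled regions are spots rather than the whole leaf.
    """
    cr, cc = spec.leaf_center
    ar, ac = spec.leaf_axes
    half_h = int(ar / np.sqrt(2.0)) - margin
    half_w = int(ac / np.sqrt(2.0)) - margin
    return CropRect(
        x1=int(cc) - half_w, y1=int(cr) - half_h, width=2 * half_w, height=2 * half_h
    )


def make_leaf_scene(spec: SceneSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene; return (RGB uint8 frame, ground-truth spot table).

    The truth table has one row per planted spot: true label, center,
    radius, planted pixel value, planted contrast ratio and rasterized area
    (the exact disc pixel count).  Raises if a spot center lies outside the
    leaf ellipse.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    img = np.full((h, w), float(spec.background_intensity))

    rr, cc = skdraw.ellipse(
        spec.leaf_center[0], spec.leaf_center[1],
        spec.leaf_axes[0], spec.leaf_axes[1], shape=(h, w),
    )
    img[rr, cc] = spec.leaf_intensity

    if spec.gradient_amplitude:
        cols = np.linspace(-1.0, 1.0, w)[None, :]
        img = img + spec.gradient_amplitude * cols

    if spec.shadow_polygon is not None and spec.shadow_opacity > 0.0:
        pr = [p[0] for p in spec.shadow_polygon]
        pc = [p[1] for p in spec.shadow_polygon]
        srr, scc = skdraw.polygon(pr, pc, shape=(h, w))
        img[srr, scc] *= 1.0 - spec.shadow_opacity

    rows = []
    for kind, spots in (("defect", spec.defects), ("noise", spec.noise)):
        for i, s in enumerate(spots):
            if not _inside_leaf(spec, s.row, s.col):
                raise ValueError(
                    f"{kind} spot at ({s.row}, {s.col}) lies outside the leaf"
                )
            drr, dcc = _disk_mask(s.row, s.col, s.radius, (h, w))
            img[drr, dcc] = s.intensity
            rows.append(
                {
                    "spot_id": f"{kind}-{i}",
                    "kind": kind,
                    "row": s.row,
                    "col": s.col,
                    "radius": s.radius,
                    "intensity": s.intensity,
                    "contrast": spec.contrast(s),
                    "planted_area_px": int(len(drr)),
                }
            )

    if spec.pixel_noise_sigma > 0.0:
        img = img + rng.normal(0.0, spec.pixel_noise_sigma, size=img.shape)

    img = np.clip(img, 0.0, 255.0)
    rgb = np.clip(
        np.round(np.stack([_TINT_R * img, _TINT_G * img, _TINT_B * img], axis=-1)),
        0,
        255,
    ).astype(np.uint8)
    truth = pd.DataFrame(
        rows,
        columns=[
            "spot_id", "kind", "row", "col", "radius",
            "intensity", "contrast", "planted_area_px",
        ],
    )
    return rgb, truth


def make_sensor_stream(spec: StreamSpec) -> list[SensorReading]:
    """Generate one channel's readings: base + drift + jitter with faults.

    Dropouts become invalid (missing) samples; outliers exceed the channel's
    physical range so downstream cleaning removes them.
    """
    rng = np.random.default_rng(spec.seed)
    readings = []
    n = int(round(spec.duration_s / spec.dt_s))
    for k in range(n):
        t = k * spec.dt_s
        jitter = rng.normal(0.0, spec.jitter_sigma) if spec.jitter_sigma else 0.0
        u_drop, u_out = rng.random(), rng.random()
        if u_drop < spec.dropout_prob:
            readings.append(
                SensorReading(spec.channel, t, float("nan"), valid=False)
            )
            continue
        value = spec.base + spec.drift_per_s * t + jitter
        if u_out < spec.outlier_prob:
            value = spec.base + spec.outlier_magnitude
        readings.append(SensorReading(spec.channel, t, float(value), valid=True))
    return readings


# ---------------------------------------------------------------------------
# scenario suites


@dataclass(frozen=True)
class SceneRecord:
    index: int
    spec: SceneSpec
    frame: np.ndarray
    truth: pd.DataFrame
    has_pest: bool
    crop: CropRect


@dataclass(frozen=True)
class ScenarioBundle:
    name: str
    seed: int
    scenes: tuple[SceneRecord, ...]


SCENARIO_NAMES = ("table3-like", "unambiguous", "boundary", "empty")

# parameter bands for planted spots; chosen once to straddle the classifier's
# linguistic boundaries (areas near 800 / 2,000 / 3,200 / 5,000 px; contrast
# ratios near 0.2 / 0.45 / 0.55 / 0.8)
_DEF_CLEAR = {"contrast": (0.68, 0.80), "radius": (30.0, 38.0)}
_NOISE_FAINT = {"contrast": (0.06, 0.15), "radius": (18.0, 28.0)}
_NOISE_TINY = {"contrast": (0.30, 0.60), "radius": (6.0, 10.0)}
_DEF_BORDER = {"contrast": (0.48, 0.62), "radius": (26.0, 41.0)}
_NOISE_BORDER_FAINT = {"contrast": (0.15, 0.25), "radius": (14.0, 18.0)}
_NOISE_BORDER_SMALL = {"contrast": (0.40, 0.50), "radius": (13.0, 16.0)}


def _place_spots(rng, spec: SceneSpec, crop: CropRect, bands, leaf_value):
    """Sample non-overlapping spot placements inside the crop region."""
    placed: list[SpotSpec] = []
    for band in bands:
        radius = rng.uniform(*band["radius"])
        contrast = rng.uniform(*band["contrast"])
        intensity = float(np.clip(leaf_value - 255.0 * contrast, 0.0, 255.0))
        for _ in range(200):  # rejection sampling for overlap
            row = rng.uniform(
                crop.y1 + radius + 12, crop.y1 + crop.height - radius - 12
            )
            col = rng.uniform(
                crop.x1 + radius + 12, crop.x1 + crop.width - radius - 12
            )
            ok = all(
                np.hypot(row - p.row, col - p.col) > radius + p.radius + 18
                for p in placed
            )
            if ok:
                placed.append(SpotSpec(row, col, radius, intensity))
                break
        else:  # no room left; skip this spot rather than overlap
            continue
    return placed


def _build_scene(
    rng,
    seed: int,
    has_pest: bool,
    defect_bands,
    noise_bands,
    gradient: float,
    shadow: bool,
) -> tuple[SceneSpec, CropRect]:
    base = SceneSpec(seed=seed, gradient_amplitude=gradient)
    crop = scene_crop(base)
    n_def = int(rng.integers(1, 3)) if has_pest else 0
    n_noise = int(rng.integers(1, 4))
    def_bands = [defect_bands[int(rng.integers(0, len(defect_bands)))] for _ in range(n_def)]
    nz_bands = [noise_bands[int(rng.integers(0, len(noise_bands)))] for _ in range(n_noise)]
    spots = _place_spots(rng, base, crop, def_bands + nz_bands, base.leaf_intensity)
    defects = tuple(spots[: len(def_bands)])
    noise = tuple(spots[len(def_bands):])
    shadow_poly = None
    opacity = 0.0
    if shadow:
        # a corner wedge clipping the top-left of the analysis region
        shadow_poly = (
            (crop.y1 - 40.0, crop.x1 - 40.0),
            (crop.y1 - 40.0, crop.x1 + 110.0),
            (crop.y1 + 90.0, crop.x1 - 40.0),
        )
        opacity = 0.18
    spec = replace(
        base,
        defects=defects,
        noise=noise,
        shadow_polygon=shadow_poly,
        shadow_opacity=opacity,
    )
    return spec, crop


def scenario_suite(name: str, seed: int = 0) -> ScenarioBundle:
    """Build a named bundle of rendered scenes with ground truth.

    * ``table3-like`` — 20 scenes whose pest-present pattern follows the
      bundled benchmark's "real" row (fifteen pest scenes).
    * ``unambiguous`` — 50 scenes, half with clearly defective spots
      (high contrast, mid-range areas), half with only noise spots.
    * ``boundary`` — 50 scenes whose spots deliberately straddle the
      classifier's linguistic boundaries; a stress suite, not a claim.
    * ``empty`` — 5 scenes with no spots at all.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    master = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)

    if name == "table3-like":
        pest_flags = [bool(v) for v in BENCHMARK_REAL]
        def_bands, nz_bands = [_DEF_CLEAR], [_NOISE_FAINT, _NOISE_TINY]
        gradient, shadow_every = 10.0, 0
    elif name == "unambiguous":
        pest_flags = [i % 2 == 0 for i in range(50)]
        def_bands, nz_bands = [_DEF_CLEAR], [_NOISE_FAINT, _NOISE_TINY]
        gradient, shadow_every = 10.0, 0
    elif name == "boundary":
        pest_flags = [i % 2 == 0 for i in range(50)]
        def_bands = [_DEF_BORDER]
        nz_bands = [_NOISE_BORDER_FAINT, _NOISE_BORDER_SMALL]
        gradient, shadow_every = 20.0, 3  # every third scene shadowed
    else:  # empty
        pest_flags = [False] * 5

    scenes = []
    children = ss.spawn(len(pest_flags))
    for i, has_pest in enumerate(pest_flags):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        if name == "empty":
            spec = SceneSpec(seed=child_seed)
            crop = scene_crop(spec)
        else:
            shadow = shadow_every > 0 and i % shadow_every == 0
            spec, crop = _build_scene(
                master, child_seed, has_pest, def_bands, nz_bands, gradient, shadow
            )
        frame, truth = make_leaf_scene(spec)
        truly_has_pest = bool((truth["kind"] == "defect").any())
        scenes.append(
            SceneRecord(
                index=i,
                spec=spec,
                frame=frame,
                truth=truth,
                has_pest=truly_has_pest,
                crop=crop,
            )
        )
    return ScenarioBundle(name=name, seed=seed, scenes=tuple(scenes))


def write_bundle(bundle: ScenarioBundle, outdir) -> Path:
    """Write a bundle as PNG scenes plus a combined ground-truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for rec in bundle.scenes:
        png = outdir / f"scene_{rec.index:03d}.png"
        iio.imwrite(png, rec.frame)
        t = rec.truth.copy()
        t.insert(0, "scene", rec.index)
        t["has_pest"] = int(rec.has_pest)
        frames.append(t)
    truth = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["scene"])
    )
    scene_rows = pd.DataFrame(
        {
            "scene": [r.index for r in bundle.scenes],
            "has_pest": [int(r.has_pest) for r in bundle.scenes],
            "crop_x1": [r.crop.x1 for r in bundle.scenes],
            "crop_y1": [r.crop.y1 for r in bundle.scenes],
            "crop_width": [r.crop.width for r in bundle.scenes],
            "crop_height": [r.crop.height for r in bundle.scenes],
        }
    )
    truth.to_csv(outdir / "ground_truth_spots.csv", index=False)
    scene_rows.to_csv(outdir / "ground_truth_scenes.csv", index=False)
    return outdir
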