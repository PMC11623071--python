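"""Frame-level image operations for leaf-spot segmentation.

The segmentation chain is: crop -> grayscale -> 5x5 Gaussian blur (sigma 8)
-> edge detection (Canny by default; Sobel/Prewitt kept for comparison) ->
hole filling -> inversion.  After inversion the candidate spots are the dark
(False) pixels; connected dark components become :class:`SpotRegion` records
carrying area, centroid, mean intensity on the original grayscale crop and a
minimal enclosing circle used later for annotation.

Conventions: images are numpy arrays, row-major, (row=0, col=0) top-left,
0-based; grayscale frames are uint8 0-255; binary frames are boolean with
True = foreground (white).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import measure as skmeasure

__all__ = [
    "CropRect",
    "SpotRegion",
    "SpotFeatures",
    "crop_frame",
    "to_grayscale",
    "gaussian_blur",
    "detect_edges",
    "fill_holes",
    "invert",
    "extract_spots",
    "compute_features",
    "min_enclosing_circle",
    "annotate",
]

GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)  # ITU-R 601 luminance


@dataclass(frozen=True)
class CropRect:
    """Axis-aligned crop: top-left corner (x1=col, y1=row) plus size."""

    x1: int
    y1: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("crop rectangle must have positive size")
        if self.x1 < 0 or self.y1 < 0:
            raise ValueError("crop rectangle origin must be non-negative")


@dataclass(frozen=True)
class SpotRegion:
    """One connected dark region with its geometry and intensity."""

    label: int
    coords: np.ndarray  # (N, 2) array of (row, col) pixel coordinates
    area: int
    centroid: tuple[float, float]  # (row, col)
    mean_intensity: float  # on the cropped grayscale original, 0-255
    circle_center: tuple[float, float]  # (row, col)
    circle_radius: float


@dataclass(frozen=True)
class SpotFeatures:
    """The two crisp inputs of the spot classifier."""

    intensity_diff: float  # |spot mean - image mean| / 255, in [0, 1]
    area: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity_diff <= 1.0:
            raise ValueError("intensity_diff outside [0, 1]")
        if self.area < 1:
            raise ValueError("area must be >= 1")


def crop_frame(frame: np.ndarray, rect: CropRect) -> np.ndarray:
    """Copy the rectangle out of the frame; rect must lie fully inside."""
    h, w = frame.shape[:2]
    if rect.x1 + rect.width > w or rect.y1 + rect.height > h:
        raise ValueError(
            f"crop {rect} exceeds frame of size {h}x{w} (rows x cols)"
        )
    return frame[rect.y1 : rect.y1 + rect.height, rect.x1 : rect.x1 + rect.width].copy()


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Luminance conversion (0.2989 R + 0.5870 G + 0.1140 B), rounded uint8.

    Grayscale input passes through unchanged.
    """
    if frame.ndim == 2:
        return frame
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise ValueError("expected HxW grayscale or HxWx3 color frame")
    r, g, b = (frame[..., i].astype(float) for i in range(3))
    lum = GRAY_WEIGHTS[0] * r + GRAY_WEIGHTS[1] * g + GRAY_WEIGHTS[2] * b
    return np.clip(np.round(lum), 0, 255).astype(np.uint8)


def gaussian_kernel(size: int = 5, sigma: float = 8.0) -> np.ndarray:
    """Normalized square Gaussian kernel (sums to 1)."""
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_blur(frame: np.ndarray, size: int = 5, sigma: float = 8.0) -> np.ndarray:
    """Convolve a grayscale frame with a size x size Gaussian, sigma as given.

    Boundary handling is symmetric (reflect); uint8 input comes back uint8.
    With the default 5x5 kernel at sigma 8 the weights are nearly uniform, so
    this is a gentle pre-smoothing ahead of edge detection.
    """
    if frame.ndim != 2:
        raise ValueError("gaussian_blur expects a grayscale frame")
    if min(frame.shape) < size:
        raise ValueError(f"frame smaller than the {size}x{size} kernel")
    kernel = gaussian_kernel(size, sigma)
    out = ndimage.convolve(frame.astype(float), kernel, mode="reflect")
    if frame.dtype == np.uint8:
        return np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out


def _auto_canny_thresholds(img: np.ndarray, sigma: float) -> tuple[float, float]:
    """High threshold from the gradient-magnitude histogram (Otsu), low = 0.4 high."""
    smoothed = skfilters.gaussian(img, sigma=sigma)
    mag = skfilters.sobel(smoothed)
    if float(mag.max()) <= 0.0:
        return 0.1, 0.2  # constant image; any positive thresholds give no edges
    high = float(skfilters.threshold_otsu(mag))
    return 0.4 * high, high


def detect_edges(
    frame: np.ndarray,
    method: str = "canny",
    low_threshold: float | None = None,
    high_threshold: float | None = None,
    smoothing_sigma: float = 1.0,
) -> np.ndarray:
    """Binary edge map of a (blurred) grayscale frame.

    ``canny`` is the pipeline default (gradient, non-maximum suppression,
    hysteresis); ``sobel``/``prewitt`` threshold the respective 3x3 gradient
    magnitude at Otsu's level and are retained for comparison runs.  When no
    thresholds are given they are selected automatically from the gradient
    magnitude histogram with low = 0.4 x high.
    """
    if frame.ndim != 2:
        raise ValueError("detect_edges expects a grayscale frame")
    img = frame.astype(float) / 255.0 if frame.dtype == np.uint8 else frame.astype(float)
    if method == "canny":
        if low_threshold is None or high_threshold is None:
            lo, hi = _auto_canny_thresholds(img, smoothing_sigma)
            low_threshold = lo if low_threshold is None else low_threshold
            high_threshold = hi if high_threshold is None else high_threshold
        return skfeature.canny(
            img,
            sigma=smoothing_sigma,
            low_threshold=low_threshold,
            high_threshold=high_threshold,
            mode="reflect",  # constant zero-padding would fabricate border edges
        )
    if method in ("sobel", "prewitt"):
        mag = skfilters.sobel(img) if method == "sobel" else skfilters.prewitt(img)
        if float(mag.max()) <= 0.0:
            return np.zeros_like(mag, dtype=bool)
        thr = high_threshold if high_threshold is not None else float(
            skfilters.threshold_otsu(mag)
        )
        return mag > thr
    raise ValueError(f"unknown edge detection method {method!r}")


def fill_holes(edges: np.ndarray) -> np.ndarray:
    """Set every background region not connected to the border to foreground."""
    if edges.dtype != bool:
        edges = edges.astype(bool)
    return ndimage.binary_fill_holes(edges)


def invert(binary: np.ndarray) -> np.ndarray:
    """Logical complement; afterwards spot pixels are the dark (False) pixels."""
    if binary.dtype != bool:
        binary = binary.astype(bool)
    return ~binary


# ---------------------------------------------------------------------------
# spot extraction and features


def _welzl(points: list[tuple[float, float]], rng: random.Random):
    """Smallest enclosing circle (Welzl, move-to-front) of 2-D points."""

    def circle_two(a, b):
        cx, cy = (a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0
        r = math.dist(a, b) / 2.0
        return (cx, cy, r)

    def circle_three(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = (
            (ax**2 + ay**2) * (by - cy)
            + (bx**2 + by**2) * (cy - ay)
            + (cx**2 + cy**2) * (ay - by)
        ) / d
        uy = (
            (ax**2 + ay**2) * (cx - bx)
            + (bx**2 + by**2) * (ax - cx)
            + (cx**2 + cy**2) * (bx - ax)
        ) / d
        return (ux, uy, math.dist((ux, uy), a))

    def contains(circ, p, eps=1e-9):
        return math.dist((circ[0], circ[1]), p) <= circ[2] + eps

    pts = points[:]
    rng.shuffle(pts)
    circ = None
    for i, p in enumerate(pts):
        if circ is not None and contains(circ, p):
            continue
        circ = (p[0], p[1], 0.0)
        for j, q in enumerate(pts[: i + 1]):
            if contains(circ, q):
                continue
            circ = circle_two(p, q)
            for k in pts[: j + 1]:
                if contains(circ, k):
                    continue
                c3 = circle_three(p, q, k)
                if c3 is not None:
                    circ = c3
    return circ


def min_enclosing_circle(coords: np.ndarray) -> tuple[tuple[float, float], float]:
    """Minimal circle enclosing the pixel centers of a region.

    Only the convex hull of the coordinates is fed to Welzl's algorithm,
    which keeps the computation O(hull size).
    """
    pts = [tuple(map(float, rc)) for rc in np.unique(coords, axis=0)]
    if len(pts) == 1:
        return (pts[0], 0.0)
    if len(pts) > 3:
        try:
            from scipy.spatial import ConvexHull

            arr = np.array(pts)
            hull = ConvexHull(arr)
            pts = [tuple(map(float, arr[v])) for v in hull.vertices]
        except Exception:
            pass  # collinear or degenerate: fall through with all points
    circ = _welzl(pts, random.Random(0))
    return ((circ[0], circ[1]), circ[2])


def extract_spots(
    processed: np.ndarray, original_gray: np.ndarray, min_area: int = 5
) -> list[SpotRegion]:
    """Connected dark components (8-connectivity) of the processed frame.

    ``processed`` is the post-inversion binary frame (True = background).
    Components touching the border are kept; components below ``min_area``
    pixels are discarded before feature extraction.  Mean intensity is
    measured on ``original_gray`` (the cropped, unblurred grayscale).
    """
    if processed.shape != original_gray.shape:
        raise ValueError("processed and grayscale frames must share a shape")
    dark = ~processed.astype(bool)
    labels = skmeasure.label(dark, connectivity=2)
    spots: list[SpotRegion] = []
    for rp in skmeasure.regionprops(labels, intensity_image=original_gray):
        if rp.area < min_area:
            continue
        center, radius = min_enclosing_circle(rp.coords)
        spots.append(
            SpotRegion(
                label=int(rp.label),
                coords=rp.coords,
                area=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                mean_intensity=float(rp.intensity_mean),
                circle_center=center,
                circle_radius=float(radius),
            )
        )
    return spots


def compute_features(spot: SpotRegion, original_gray: np.ndarray) -> SpotFeatures:
    """Crisp classifier inputs for one spot.

    intensity_diff = |mean over spot pixels - mean over the whole cropped
    grayscale image| / 255; area is the spot's pixel count.
    """
    image_mean = float(original_gray.mean())
    diff = abs(spot.mean_intensity - image_mean) / 255.0
    return SpotFeatures(intensity_diff=min(diff, 1.0), area=spot.area)


def annotate(
    frame: np.ndarray,
    spots: list[SpotRegion],
    defect_flags: list[bool],
    margin: int = 3,
) -> np.ndarray:
    """Draw a red circle around each defect spot; noise spots stay unmarked.

    Grayscale frames are promoted to RGB; all other pixels are untouched.
    """
    if len(spots) != len(defect_flags):
        raise ValueError("spots and defect_flags must align")
    if frame.ndim == 2:
        rgb = np.stack([frame] * 3, axis=-1).astype(np.uint8)
    else:
        rgb = frame.astype(np.uint8).copy()
    for spot, is_defect in zip(spots, defect_flags):
        if not is_defect:
            continue
        r0, c0 = (int(round(v)) for v in spot.circle_center)
        radius = int(math.ceil(spot.circle_radius)) + margin
        rr, cc = skdraw.circle_perimeter(r0, c0, radius, shape=rgb.shape[:2])
        rgb[rr, cc] = (255, 0, 0)
    return rgb
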