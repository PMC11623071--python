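"""Image operations: crop, grayscale, blur, edges, fill, spots, features."""

import math
from collections import deque

import numpy as np
import pytest

from plantwatch.imaging import (
    CropRect,
    SpotFeatures,
    annotate,
    compute_features,
    crop_frame,
    detect_edges,
    extract_spots,
    fill_holes,
    gaussian_blur,
    gaussian_kernel,
    invert,
    min_enclosing_circle,
    to_grayscale,
)


def border_flood_complement(binary):
    """Independent oracle: pixels NOT reachable from the border through
    4-connected background — i.e. what hole filling turns to foreground,
    computed by a hand-rolled BFS rather than scipy."""
    h, w = binary.shape
    reached = np.zeros_like(binary, dtype=bool)
    q = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not binary[r, c] and not reached[r, c]:
                reached[r, c] = True
                q.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not binary[r, c] and not reached[r, c]:
                reached[r, c] = True
                q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not binary[rr, cc] and not reached[rr, cc]:
                reached[rr, cc] = True
                q.append((rr, cc))
    return ~reached  # outline pixels plus enclosed interior


class TestCrop:
    def test_full_frame_identity(self):
        f = np.arange(100, dtype=np.uint8).reshape(10, 10)
        out = crop_frame(f, CropRect(0, 0, 10, 10))
        assert np.array_equal(out, f)

    def test_coordinate_bookkeeping(self):
        f = np.arange(100, dtype=np.uint8).reshape(10, 10)
        out = crop_frame(f, CropRect(2, 2, 5, 5))
        assert out.shape == (5, 5)
        assert out[0, 0] == f[2, 2]

    def test_single_pixel(self):
        f = np.arange(100, dtype=np.uint8).reshape(10, 10)
        assert crop_frame(f, CropRect(3, 4, 1, 1)).item() == f[4, 3]

    def test_out_of_bounds_rejected(self):
        f = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError):
            crop_frame(f, CropRect(8, 8, 5, 5))


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((100, 200, 50), 153)],
    )
    def test_luminance_weights(self, rgb, expected):
        frame = np.zeros((2, 2, 3), dtype=np.uint8)
        frame[:] = rgb
        assert to_grayscale(frame)[0, 0] == expected

    def test_grayscale_passthrough(self):
        g = np.full((4, 4), 77, dtype=np.uint8)
        assert to_grayscale(g) is g


class TestBlur:
    def test_constant_image_preserved(self):
        f = np.full((20, 20), 123, dtype=np.uint8)
        assert np.array_equal(gaussian_blur(f), f)

    def test_mass_conserved_for_isolated_pixel(self):
        f = np.zeros((31, 31))
        f[15, 15] = 1000.0
        out = gaussian_blur(f)
        assert out.sum() == pytest.approx(1000.0)
        assert np.count_nonzero(out) == 25  # spread over the 5x5 neighbourhood

    def test_kernel_center_weight_by_direct_summation(self):
        # oracle: evaluate exp(-r^2 / (2 sigma^2)) on the 5x5 grid and normalize
        total = sum(
            math.exp(-(i * i + j * j) / (2 * 64.0))
            for i in range(-2, 3)
            for j in range(-2, 3)
        )
        assert gaussian_kernel(5, 8.0)[2, 2] == pytest.approx(1.0 / total, abs=1e-12)

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((3, 3), dtype=np.uint8))


class TestEdges:
    def test_constant_image_has_no_edges(self):
        f = np.full((32, 32), 99, dtype=np.uint8)
        for method in ("canny", "sobel", "prewitt"):
            assert not detect_edges(f, method).any()

    def test_canny_thin_line_on_step_edge(self):
        f = np.zeros((40, 40), dtype=np.uint8)
        f[:, 20:] = 100
        edges = detect_edges(f, "canny")
        # a thin vertical line near the step, one pixel per interior row
        cols = np.where(edges.any(axis=0))[0]
        assert len(cols) >= 1 and np.all(np.abs(cols - 19.5) < 3)
        interior = edges[5:-5]
        assert np.all(interior.sum(axis=1) <= 2)

    def test_gradient_methods_mark_the_step(self):
        f = np.zeros((40, 40), dtype=np.uint8)
        f[:, 20:] = 100
        for method in ("sobel", "prewitt"):
            edges = detect_edges(f, method)
            cols = np.where(edges.any(axis=0))[0]
            assert len(cols) >= 1 and np.all(np.abs(cols - 19.5) < 3)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            detect_edges(np.zeros((10, 10), dtype=np.uint8), "laplace")


class TestFillAndInvert:
    def test_closed_outline_becomes_disc(self):
        from skimage.draw import circle_perimeter

        edges = np.zeros((40, 40), dtype=bool)
        rr, cc = circle_perimeter(20, 20, 10)
        edges[rr, cc] = True
        filled = fill_holes(edges)
        oracle = border_flood_complement(edges)
        assert np.array_equal(filled, oracle)
        assert filled.sum() > edges.sum()

    def test_open_outline_unchanged(self):
        edges = np.zeros((20, 20), dtype=bool)
        edges[5, 5:15] = True  # a line has no interior
        assert np.array_equal(fill_holes(edges), edges)

    def test_empty_frame_stays_empty(self):
        assert not fill_holes(np.zeros((10, 10), dtype=bool)).any()

    def test_invert_is_involution(self):
        rng = np.random.default_rng(3)
        b = rng.random((15, 15)) > 0.5
        assert np.array_equal(invert(invert(b)), b)

    def test_invert_all_ones(self):
        assert not invert(np.ones((5, 5), dtype=bool)).any()


class TestSpots:
    def test_blank_frame_yields_no_spots(self):
        processed = np.ones((20, 20), dtype=bool)  # all background
        assert extract_spots(processed, np.zeros((20, 20), dtype=np.uint8)) == []

    def test_blob_area_centroid_and_intensity(self):
        processed = np.ones((20, 20), dtype=bool)
        processed[5:9, 5:10] = False  # 4x5 dark blob
        gray = np.full((20, 20), 200, dtype=np.uint8)
        gray[5:9, 5:10] = 30
        spots = extract_spots(processed, gray)
        assert len(spots) == 1
        s = spots[0]
        # brute-force pixel enumeration oracle
        coords = [(r, c) for r in range(5, 9) for c in range(5, 10)]
        assert s.area == len(coords)
        assert s.centroid[0] == pytest.approx(np.mean([r for r, _ in coords]))
        assert s.centroid[1] == pytest.approx(np.mean([c for _, c in coords]))
        assert s.mean_intensity == pytest.approx(30.0)

    def test_separated_blobs_are_distinct(self):
        processed = np.ones((20, 20), dtype=bool)
        processed[2:5, 2:5] = False
        processed[10:13, 10:13] = False
        spots = extract_spots(processed, np.zeros((20, 20), dtype=np.uint8))
        assert len(spots) == 2

    def test_diagonal_contact_is_one_component(self):
        processed = np.ones((10, 10), dtype=bool)
        processed[2:5, 2:5] = False
        processed[5:8, 5:8] = False  # touches only at the (4,4)/(5,5) diagonal
        spots = extract_spots(processed, np.zeros((10, 10), dtype=np.uint8))
        assert len(spots) == 1  # 8-connectivity joins them

    def test_min_area_floor(self):
        processed = np.ones((20, 20), dtype=bool)
        processed[1, 1:4] = False  # 3 px, below the default floor of 5
        assert extract_spots(processed, np.zeros((20, 20), dtype=np.uint8)) == []

    def test_border_touching_spot_is_kept(self):
        processed = np.ones((20, 20), dtype=bool)
        processed[0:4, 0:4] = False
        assert len(extract_spots(processed, np.zeros((20, 20), dtype=np.uint8))) == 1


class TestMinEnclosingCircle:
    def test_two_points(self):
        (cr, cc), r = min_enclosing_circle(np.array([[0, 0], [0, 10]]))
        assert (cr, cc) == pytest.approx((0.0, 5.0))
        assert r == pytest.approx(5.0)

    def test_square_uses_diagonal(self):
        pts = np.array([[0, 0], [0, 10], [10, 0], [10, 10]])
        (_, _), r = min_enclosing_circle(pts)
        assert r == pytest.approx(math.sqrt(200) / 2)

    def test_encloses_and_is_minimal_vs_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.integers(0, 30, size=(12, 2))
            (cr, cc), r = min_enclosing_circle(pts)
            dists = np.hypot(pts[:, 0] - cr, pts[:, 1] - cc)
            assert np.all(dists <= r + 1e-6)
            # brute force: best circle from all pairs and triples
            best = np.inf
            n = len(pts)
            for i in range(n):
                for j in range(i + 1, n):
                    c = (pts[i] + pts[j]) / 2.0
                    rr = np.hypot(*(pts[i] - c))
                    if np.all(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= rr + 1e-9):
                        best = min(best, rr)
                    for k in range(j + 1, n):
                        ax, ay = pts[i]; bx, by = pts[j]; cx, cy = pts[k]
                        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                        if abs(d) < 1e-12:
                            continue
                        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
                              + (cx**2 + cy**2) * (ay - by)) / d
                        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
                              + (cx**2 + cy**2) * (bx - ax)) / d
                        rr = math.dist((ux, uy), (ax, ay))
                        if np.all(np.hypot(pts[:, 0] - ux, pts[:, 1] - uy) <= rr + 1e-9):
                            best = min(best, rr)
            assert r == pytest.approx(best, abs=1e-6)


class TestFeaturesAndAnnotation:
    def test_zero_diff_when_spot_matches_image(self):
        processed = np.ones((10, 10), dtype=bool)
        processed[2:5, 2:5] = False
        gray = np.full((10, 10), 90, dtype=np.uint8)
        spot = extract_spots(processed, gray)[0]
        assert compute_features(spot, gray).intensity_diff == 0.0

    def test_half_scale_difference(self):
        # spot mean 30, image mean (30+255)/2 = 142.5 -> diff = 112.5/255
        gray = np.zeros((10, 20), dtype=np.uint8)
        gray[:, :10] = 30
        gray[:, 10:] = 255
        processed = np.ones_like(gray, dtype=bool)
        processed[:, :10] = False
        spot = extract_spots(processed, gray)[0]
        f = compute_features(spot, gray)
        assert f.intensity_diff == pytest.approx((142.5 - 30) / 255)

    def test_features_validate_ranges(self):
        with pytest.raises(ValueError):
            SpotFeatures(intensity_diff=1.2, area=10)
        with pytest.raises(ValueError):
            SpotFeatures(intensity_diff=0.5, area=0)

    def test_annotation_marks_only_defects(self):
        gray = np.full((40, 40), 180, dtype=np.uint8)
        processed = np.ones((40, 40), dtype=bool)
        processed[10:20, 10:20] = False
        spots = extract_spots(processed, gray)
        no_marks = annotate(gray, spots, [False])
        assert np.array_equal(no_marks[..., 0], gray)  # promotion only
        marked = annotate(gray, spots, [True])
        red = (marked[..., 0] == 255) & (marked[..., 1] == 0) & (marked[..., 2] == 0)
        assert red.any()
        untouched = ~red
        assert np.array_equal(marked[untouched][:, 0], gray[untouched])
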