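"""Tiling: tissue masking, annotation rasterisation, patch extraction."""

from __future__ import annotations

import numpy as np
import pytest

from histoclust.tiling import (
    AnnotationSet,
    SlideImage,
    compute_tissue_mask,
    extract_patches,
    patch_manifest,
    rasterise_annotations,
)


def _slide(arr: np.ndarray, mpp: float = 1.0, sid: str = "s") -> SlideImage:
    return SlideImage(slide_id=sid, pixel_array=arr.astype(np.uint8), microns_per_pixel=mpp)


def _pip_oracle(polygon: np.ndarray, h: int, w: int) -> np.ndarray:
    """Brute-force even-odd ray casting on pixel centres."""
    mask = np.zeros((h, w), dtype=bool)
    n = len(polygon)
    for r in range(h):
        for c in range(w):
            px, py = c + 0.5, r + 0.5
            inside = False
            for i in range(n):
                x1, y1 = polygon[i]
                x2, y2 = polygon[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    xcross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xcross:
                        inside = not inside
            mask[r, c] = inside
    return mask


class TestTissueMask:
    def test_pure_white_raster_has_no_tissue(self):
        slide = _slide(np.full((32, 32, 3), 255))
        with pytest.warns(UserWarning, match="all background"):
            mask = compute_tissue_mask(slide)
        assert not mask.any()

    def test_saturated_strip_detected_exactly(self):
        arr = np.full((60, 80, 3), 255)
        arr[20:40, 10:70] = (230, 140, 160)  # saturated pink strip
        mask = compute_tissue_mask(_slide(arr))
        expected = np.zeros((60, 80), dtype=bool)
        expected[20:40, 10:70] = True
        assert np.array_equal(mask, expected)

    def test_checkerboard_covers_half(self):
        arr = np.full((64, 64, 3), 255)
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        board = ((rr // 8 + cc // 8) % 2 == 0)
        arr[board] = (220, 120, 150)
        mask = compute_tissue_mask(_slide(arr))
        assert abs(mask.mean() - 0.5) <= 0.01

    def test_otsu_fallback_separates_tissue(self):
        arr = np.full((40, 40, 3), 255)
        arr[:20] = (220, 120, 150)
        mask = compute_tissue_mask(_slide(arr), saturation_threshold=None)
        assert mask[:20].all() and not mask[20:].any()


class TestRasteriseAnnotations:
    def test_rectangle_area_exact(self):
        slide = _slide(np.zeros((200, 200, 3)))
        poly = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
        mask = rasterise_annotations(slide, AnnotationSet("s", [poly]))
        assert int(mask.sum()) == 10_000
        assert mask[:100, :100].all()

    def test_disjoint_rectangles_union(self):
        slide = _slide(np.zeros((100, 100, 3)))
        a = np.array([[0, 0], [20, 0], [20, 30], [0, 30]], dtype=float)
        b = np.array([[50, 50], [90, 50], [90, 80], [50, 80]], dtype=float)
        mask = rasterise_annotations(slide, AnnotationSet("s", [a, b]))
        assert int(mask.sum()) == 20 * 30 + 40 * 30

    def test_random_simple_polygon_matches_ray_casting(self):
        rng = np.random.default_rng(3)
        # star-shaped simple polygon: vertices sorted by angle around centre
        angles = np.sort(rng.uniform(0, 2 * np.pi, 9))
        radii = rng.uniform(5, 18, 9)
        centre = np.array([20.0, 20.0])
        poly = centre + np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)
        slide = _slide(np.zeros((40, 40, 3)))
        mask = rasterise_annotations(slide, AnnotationSet("s", [poly]))
        assert np.array_equal(mask, _pip_oracle(poly, 40, 40))

    def test_self_intersecting_polygon_rejected_by_index(self):
        slide = _slide(np.zeros((50, 50, 3)))
        ok = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
        with pytest.raises(ValueError, match="polygon 1"):
            rasterise_annotations(slide, AnnotationSet("s", [ok, bowtie]))

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            AnnotationSet("s", [np.array([[0, 0], [1, 1]], dtype=float)])


class TestExtractPatches:
    def test_full_tissue_grid_count(self):
        arr = np.full((512, 512, 3), (220, 120, 150))
        slide = _slide(arr, mpp=1.0)
        tissue = np.ones((512, 512), dtype=bool)
        patches = extract_patches(slide, tissue, patch_microns=256, patch_pixels=256)
        assert len(patches) == 4
        assert sorted(p.key for p in patches) == [
            ("s", 0, 0), ("s", 0, 1), ("s", 1, 0), ("s", 1, 1)
        ]

    def test_half_tumour_labels_match_bruteforce(self):
        h = w = 256
        slide = _slide(np.full((h, w, 3), (220, 120, 150)), mpp=1.0)
        tissue = np.ones((h, w), dtype=bool)
        tumour = np.zeros((h, w), dtype=bool)
        tumour[:, :150]
        tumour[:, :150] = True
        window = 64
        patches = extract_patches(slide, tissue, tumour, patch_microns=64, patch_pixels=64)
        assert len(patches) == 16
        for p in patches:
            r0, c0 = p.grid_row * window, p.grid_col * window
            frac = tumour[r0 : r0 + window, c0 : c0 + window].mean()
            assert p.tumour_fraction == pytest.approx(frac)
            assert p.weak_label == ("tumour" if frac > 0.5 else "non_tumour")
        # boundary column (cols 128..191) has 22/64 tumour -> non_tumour
        boundary = [p for p in patches if p.grid_col == 2]
        assert all(p.weak_label == "non_tumour" for p in boundary)
        left = [p for p in patches if p.grid_col < 2]
        assert all(p.weak_label == "tumour" for p in left)

    def test_all_background_slide_yields_nothing(self):
        slide = _slide(np.full((256, 256, 3), 255), mpp=1.0)
        tissue = np.zeros((256, 256), dtype=bool)
        with pytest.warns(UserWarning, match="tissue filter"):
            assert extract_patches(slide, tissue, patch_microns=64, patch_pixels=64) == []

    def test_subpixel_patch_size_errors(self):
        slide = _slide(np.zeros((64, 64, 3)), mpp=2.0)
        with pytest.raises(ValueError, match="smaller than one source pixel"):
            extract_patches(slide, np.ones((64, 64), dtype=bool), patch_microns=1.0)

    def test_slide_smaller_than_window_warns_empty(self):
        slide = _slide(np.zeros((32, 32, 3)), mpp=1.0)
        with pytest.warns(UserWarning, match="smaller than one"):
            out = extract_patches(slide, np.ones((32, 32), dtype=bool), patch_microns=64)
        assert out == []

    def test_resampling_to_patch_pixels(self):
        arr = np.full((128, 128, 3), (220, 120, 150))
        slide = _slide(arr, mpp=2.0)  # 125 um -> 62 px window, resampled to 64
        patches = extract_patches(
            slide, np.ones((128, 128), dtype=bool), patch_microns=125, patch_pixels=64
        )
        assert patches and all(p.pixels.shape == (64, 64, 3) for p in patches)


class TestGridInvariants:
    def test_phantom_windows_disjoint_and_inside(self, phantom_half):
        slide, ann, truth = phantom_half
        patches = extract_patches(
            slide, truth.tissue_mask, truth.tumour_mask, patch_pixels=64
        )
        window = 64
        seen = set()
        h, w = slide.shape
        for p in patches:
            assert p.key not in seen
            seen.add(p.key)
            assert p.grid_row * window + window <= h
            assert p.grid_col * window + window <= w

    def test_phantom_labels_reproduced_by_pixel_counting(self, phantom_half):
        slide, ann, truth = phantom_half
        patches = extract_patches(
            slide, truth.tissue_mask, truth.tumour_mask, patch_pixels=64
        )
        window = 64
        for p in patches:
            r0, c0 = p.grid_row * window, p.grid_col * window
            win = truth.tumour_mask[r0 : r0 + window, c0 : c0 + window]
            label = "tumour" if win.sum() / win.size > 0.5 else "non_tumour"
            assert p.weak_label == label

    def test_manifest_deterministic(self, phantom_half):
        slide, ann, truth = phantom_half
        runs = []
        for _ in range(2):
            patches = extract_patches(
                slide, truth.tissue_mask, truth.tumour_mask, patch_pixels=64
            )
            runs.append(patch_manifest(patches).to_csv(index=False))
        assert runs[0] == runs[1]


def test_slide_image_validation():
    with pytest.raises(ValueError, match="3"):
        SlideImage("s", np.zeros((4, 4)), 1.0)
    with pytest.raises(ValueError, match="microns_per_pixel"):
        SlideImage("s", np.zeros((4, 4, 3)), -1.0)
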