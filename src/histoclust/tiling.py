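"""Tissue-aware tiling of annotated slide images.

Converts an RGB slide raster plus polygonal tumour outlines into a grid of
fixed-size patches, each carrying its tissue fraction, tumour fraction and
a weak tumour / non-tumour label.  The physical tile scale (microns) and the
output pixel size are decoupled: a window of ``patch_microns`` on the slide
is resampled to ``patch_pixels`` square.

Conventions (fixed for reproducible manifests):

* pixel coordinates are 0-based, origin at the top-left, ``row`` = y,
  ``col`` = x;
* grid windows are half-open ``[r, r+s) x [c, c+s)`` with stride equal to
  the window edge (non-overlapping);
* a pixel belongs to a polygon iff its centre ``(col + 0.5, row + 0.5)``
  lies inside the polygon (even-odd rule; polygons are required to be
  simple, so even-odd and winding agree), with the union taken across
  polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.transform import resize

__all__ = [
    "Diagnosis",
    "SlideImage",
    "AnnotationSet",
    "Patch",
    "compute_tissue_mask",
    "rasterise_annotations",
    "extract_patches",
    "patch_manifest",
]

DEFAULT_SATURATION_THRESHOLD = 0.07
DEFAULT_TISSUE_THRESHOLD = 0.5
TUMOUR_MAJORITY_THRESHOLD = 0.5


class Diagnosis(str, Enum):
    """Slide-level pathology label for primary liver cancer."""

    HCC = "HCC"
    ICCA = "iCCA"
    CHCC_CCA = "cHCC-CCA"
    UNKNOWN = "unknown"


@dataclass
class SlideImage:
    """A single-resolution RGB slide raster with physical pixel size."""

    slide_id: str
    pixel_array: np.ndarray  # (H, W, 3) uint8
    microns_per_pixel: float
    diagnosis_label: Diagnosis = Diagnosis.UNKNOWN

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixel_array)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(
                f"slide {self.slide_id!r}: raster must be (H, W, 3), got {arr.shape}"
            )
        if not np.isfinite(self.microns_per_pixel) or self.microns_per_pixel <= 0:
            raise ValueError(
                f"slide {self.slide_id!r}: microns_per_pixel must be finite and > 0"
            )
        self.pixel_array = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixel_array.shape[:2]


@dataclass
class AnnotationSet:
    """Closed tumour-outline polygons in pixel coordinates (x=col, y=row)."""

    slide_id: str
    tumour_polygons: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for i, poly in enumerate(self.tumour_polygons):
            pts = np.asarray(poly, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise ValueError(
                    f"annotation {i} of slide {self.slide_id!r}: polygon needs "
                    f">= 3 (x, y) vertices, got shape {pts.shape}"
                )
            cleaned.append(pts)
        self.tumour_polygons = cleaned


@dataclass
class Patch:
    """One fixed-size RGB tile cut from the slide grid."""

    slide_id: str
    grid_row: int
    grid_col: int
    pixels: np.ndarray  # (patch_pixels, patch_pixels, 3) uint8
    tissue_fraction: float
    tumour_fraction: float

    @property
    def weak_label(self) -> str:
        return "tumour" if self.tumour_fraction > TUMOUR_MAJORITY_THRESHOLD else "non_tumour"

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.slide_id, self.grid_row, self.grid_col)


def compute_tissue_mask(
    slide: SlideImage,
    saturation_threshold: float | None = DEFAULT_SATURATION_THRESHOLD,
) -> np.ndarray:
    """Boolean tissue mask: True where the pixel looks like stained tissue.

    Stained tissue (pink/orange on a near-white background) is far more
    saturated than background, so the mask thresholds the HSV saturation
    channel.  With ``saturation_threshold=None`` an Otsu threshold on the
    saturation histogram is used instead.
    """
    arr = slide.pixel_array
    if arr.size == 0:
        raise ValueError(f"slide {slide.slide_id!r}: empty raster")
    sat = rgb2hsv(arr)[..., 1]
    if saturation_threshold is None:
        try:
            saturation_threshold = float(threshold_otsu(sat))
        except ValueError:  # constant image
            saturation_threshold = DEFAULT_SATURATION_THRESHOLD
    mask = sat > saturation_threshold
    if not mask.any():
        warnings.warn(
            f"slide {slide.slide_id!r}: no tissue found (all background)",
            stacklevel=2,
        )
    return mask


def _validate_polygons(ann: AnnotationSet) -> list[Polygon]:
    polys = []
    for i, pts in enumerate(ann.tumour_polygons):
        poly = Polygon(pts)
        if not poly.is_valid:
            raise ValueError(
                f"annotation polygon {i} of slide {ann.slide_id!r} is invalid "
                f"(self-intersecting or degenerate)"
            )
        if poly.area == 0:
            raise ValueError(
                f"annotation polygon {i} of slide {ann.slide_id!r} has zero area"
            )
        polys.append(poly)
    return polys


def rasterise_annotations(slide: SlideImage, ann: AnnotationSet) -> np.ndarray:
    """Rasterise tumour outlines to a boolean mask over the slide raster.

    A pixel is tumour iff its centre lies inside at least one polygon.
    Self-intersecting polygons are rejected with the offending index.
    """
    h, w = slide.shape
    mask = np.zeros((h, w), dtype=bool)
    polys = _validate_polygons(ann)
    if not polys:
        return mask
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    for poly in polys:
        # clip to slide bounds to keep the point-in-polygon test cheap
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.floor(minx)), 0)
        r0 = max(int(np.floor(miny)), 0)
        c1 = min(int(np.ceil(maxx)) + 1, w)
        r1 = min(int(np.ceil(maxy)) + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        sub = shapely.contains_xy(poly, cols[r0:r1, c0:c1], rows[r0:r1, c0:c1])
        mask[r0:r1, c0:c1] |= sub
    return mask


def extract_patches(
    slide: SlideImage,
    tissue_mask: np.ndarray,
    tumour_mask: np.ndarray | None = None,
    patch_microns: float = 125.0,
    patch_pixels: int = 256,
    tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD,
) -> list[Patch]:
    """Cut the slide into a non-overlapping grid and keep tissue patches.

    The source window edge is ``round(patch_microns / microns_per_pixel)``
    pixels; each retained window is resampled (bilinear) to
    ``patch_pixels`` square.  A patch is retained iff its tissue fraction
    exceeds ``tissue_threshold``; its weak label is tumour iff more than
    half of the window's pixels are inside the tumour mask.
    """
    h, w = slide.shape
    if patch_microns < slide.microns_per_pixel:
        raise ValueError(
            f"patch_microns={patch_microns} is smaller than one source pixel "
            f"({slide.microns_per_pixel} um)"
        )
    window = int(round(patch_microns / slide.microns_per_pixel))
    if window > h or window > w:
        warnings.warn(
            f"slide {slide.slide_id!r} ({h}x{w}) is smaller than one "
            f"{window}px window; no patches extracted",
            stacklevel=2,
        )
        return []
    if tissue_mask.shape != (h, w):
        raise ValueError("tissue_mask shape does not match the slide raster")
    if tumour_mask is None:
        tumour_mask = np.zeros((h, w), dtype=bool)
    if tumour_mask.shape != (h, w):
        raise ValueError("tumour_mask shape does not match the slide raster")

    patches: list[Patch] = []
    n_rows = h // window
    n_cols = w // window
    for gr in range(n_rows):
        for gc in range(n_cols):
            r0, c0 = gr * window, gc * window
            win_tissue = tissue_mask[r0 : r0 + window, c0 : c0 + window]
            tissue_fraction = float(win_tissue.mean())
            if tissue_fraction <= tissue_threshold:
                continue
            win_tumour = tumour_mask[r0 : r0 + window, c0 : c0 + window]
            tumour_fraction = float(win_tumour.mean())
            tile = slide.pixel_array[r0 : r0 + window, c0 : c0 + window]
            if window != patch_pixels:
                tile = resize(
                    tile.astype(float),
                    (patch_pixels, patch_pixels, 3),
                    order=1,
                    mode="reflect",
                    anti_aliasing=False,
                    preserve_range=True,
                )
                tile = np.clip(np.rint(tile), 0, 255)
            patches.append(
                Patch(
                    slide_id=slide.slide_id,
                    grid_row=gr,
                    grid_col=gc,
                    pixels=tile.astype(np.uint8),
                    tissue_fraction=tissue_fraction,
                    tumour_fraction=tumour_fraction,
                )
            )
    if not patches:
        warnings.warn(f"slide {slide.slide_id!r}: no patch passed the tissue filter", stacklevel=2)
    return patches


def patch_manifest(patches: Sequence[Patch]) -> pd.DataFrame:
    """Deterministic (row-major sorted) manifest of extracted patches."""
    rows = [
        {
            "slide_id": p.slide_id,
            "grid_row": p.grid_row,
            "grid_col": p.grid_col,
            "tissue_fraction": p.tissue_fraction,
            "tumour_fraction": p.tumour_fraction,
            "weak_label": p.weak_label,
        }
        for p in patches
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "slide_id",
            "grid_row",
            "grid_col",
            "tissue_fraction",
            "tumour_fraction",
            "weak_label",
        ],
    )
    return df.sort_values(["slide_id", "grid_row", "grid_col"]).reset_index(drop=True)
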