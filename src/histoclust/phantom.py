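"""Synthetic biopsy phantoms with exact ground truth.

Each phantom emulates a needle-biopsy slide at desk scale: an elongated,
gently curved tissue strip on a near-white background.  Part of the strip
is tumour, outlined by annotation polygons; the tumour is split into two
procedurally textured contingents that echo the two ends of the primary
liver cancer spectrum:

* texture A (HCC-like): homogeneous sheets of large packed cells with
  eosinophilic (pink) cytoplasm and small dark nuclei, no stroma;
* texture B (iCCA-like): dark ring/gland motifs embedded in
  saffron-orange fibrous stroma bands.

Textures are procedural (blobs and rings, not generative models) so the
per-pixel class map is exact and generation is CPU-cheap.  Geometry is
built with shapely and rasterised with the same pixel-centre convention
as the tiling module, which makes the emitted annotation polygons and
truth masks consistent by construction.

All randomness flows from the spec seed: identical specs give
byte-identical slides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPolygon, Polygon, box

from .tiling import AnnotationSet, Diagnosis, Patch, SlideImage

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortData",
    "generate_slide",
    "generate_cohort",
    "pixel_statistic_accuracy",
]

# class-map codes
BACKGROUND, NON_TUMOUR, TEXTURE_A, TEXTURE_B = 0, 1, 2, 3

# colour palette (RGB uint8)
_BG = np.array([250.0, 250.0, 250.0])
_NON_TUMOUR_BASE = np.array([235.0, 185.0, 195.0])  # pale pink parenchyma
_A_BASE = np.array([228.0, 135.0, 155.0])  # eosinophilic pink sheet
_A_CELL = np.array([238.0, 120.0, 150.0])
_A_NUCLEUS = np.array([95.0, 45.0, 115.0])
_B_STROMA = np.array([228.0, 158.0, 75.0])  # saffron-orange fibrous stroma
_B_RING = np.array([85.0, 65.0, 135.0])  # dark gland ring
_B_LUMEN = np.array([244.0, 228.0, 215.0])


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom biopsy slide.

    The default physical scale makes a 125 um tile exactly 64 px, so the
    whole pipeline can run at desk scale without resampling.
    """

    slide_id: str = "phantom"
    canvas_height: int = 448
    canvas_width: int = 640
    microns_per_pixel: float = 125.0 / 64.0
    strip_width: float = 140.0  # px
    strip_amplitude: float = 55.0  # px, curvature of the strip centreline
    strip_margin: float = 30.0  # px, clearance from the canvas edge
    tumour_fraction_of_tissue: float = 0.6
    contingent_fraction_A: float = 1.0
    cell_radius: float = 3.5  # texture A cell size, px
    ring_radius: float = 6.0  # texture B gland outer radius, px
    ring_thickness: float = 2.0
    stroma_band_period: float = 18.0  # px, stroma stripe wavelength
    noise_level: float = 2.0  # additive Gaussian noise, uint8 std
    interleaved_mixing: bool = False  # salt-and-pepper contingents (stress mode)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tumour_fraction_of_tissue", "contingent_fraction_A"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.strip_width + 2 * self.strip_amplitude + 2 * self.strip_margin > self.canvas_height:
            raise ValueError(
                f"strip (width {self.strip_width}, amplitude {self.strip_amplitude}) "
                f"does not fit a canvas of height {self.canvas_height}"
            )


@dataclass
class PhantomTruth:
    """Exact per-pixel ground truth of a generated phantom."""

    tissue_mask: np.ndarray  # bool (H, W)
    tumour_mask: np.ndarray  # bool, subset of tissue
    class_map: np.ndarray  # uint8 codes {0: bg, 1: non-tumour, 2: A, 3: B}
    contingent_fraction_A: float  # realised A share of tumour pixels

    def __post_init__(self) -> None:
        if np.any(self.tumour_mask & ~self.tissue_mask):
            raise ValueError("truth inconsistent: tumour pixels outside tissue")

    def tile_truth(self, window: int) -> pd.DataFrame:
        """Per-grid-window fractions and majority labels from the class map."""
        h, w = self.class_map.shape
        rows = []
        for gr in range(h // window):
            for gc in range(w // window):
                win = self.class_map[
                    gr * window : (gr + 1) * window, gc * window : (gc + 1) * window
                ]
                n = win.size
                n_tissue = int((win != BACKGROUND).sum())
                n_tumour = int(((win == TEXTURE_A) | (win == TEXTURE_B)).sum())
                n_a = int((win == TEXTURE_A).sum())
                n_b = int((win == TEXTURE_B).sum())
                rows.append(
                    {
                        "grid_row": gr,
                        "grid_col": gc,
                        "tissue_fraction": n_tissue / n,
                        "tumour_fraction": n_tumour / n,
                        "weak_label": "tumour" if n_tumour / n > 0.5 else "non_tumour",
                        "texture_A_fraction_of_tumour": n_a / n_tumour if n_tumour else np.nan,
                        "majority_texture": (
                            "A" if n_a > n_b else ("B" if n_b > n_a else "tie")
                        )
                        if n_tumour
                        else "",
                    }
                )
        return pd.DataFrame(rows)


def _pixel_centres(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    return cols, rows


def _rasterise(geom, h: int, w: int) -> np.ndarray:
    if geom.is_empty:
        return np.zeros((h, w), dtype=bool)
    cols, rows = _pixel_centres(h, w)
    return shapely.contains_xy(geom, cols, rows)


def _column_cut(mask: np.ndarray, start_col: int, target_pixels: float) -> int:
    """Smallest column c such that mask[:, start_col:c] holds >= target pixels."""
    csum = np.cumsum(mask[:, start_col:].sum(axis=0))
    idx = int(np.searchsorted(csum, target_pixels))
    return start_col + min(idx + 1, mask.shape[1] - start_col)


def _paint_disk(canvas, mask, r, c, radius, colour):
    h, w = mask.shape
    rad = int(np.ceil(radius))
    r0, r1 = max(int(r) - rad, 0), min(int(r) + rad + 1, h)
    c0, c1 = max(int(c) - rad, 0), min(int(c) + rad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    disk = ((yy - r) ** 2 + (xx - c) ** 2 <= radius**2) & mask[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1][disk] = colour


def _paint_ring(canvas, mask, r, c, outer, thickness, ring_col, lumen_col):
    h, w = mask.shape
    rad = int(np.ceil(outer))
    r0, r1 = max(int(r) - rad, 0), min(int(r) + rad + 1, h)
    c0, c1 = max(int(c) - rad, 0), min(int(c) + rad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - r) ** 2 + (xx - c) ** 2
    local = mask[r0:r1, c0:c1]
    inner = outer - thickness
    canvas[r0:r1, c0:c1][(d2 <= outer**2) & (d2 > inner**2) & local] = ring_col
    canvas[r0:r1, c0:c1][(d2 <= inner**2) & local] = lumen_col


def _scatter_positions(rng, mask: np.ndarray, spacing: float) -> np.ndarray:
    """Roughly Poisson-scattered points inside the mask."""
    n_true = int(mask.sum())
    if n_true == 0:
        return np.empty((0, 2))
    n = max(1, int(1.4 * n_true / spacing**2))
    idx_r, idx_c = np.nonzero(mask)
    pick = rng.integers(0, len(idx_r), size=n)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    return np.stack([idx_r[pick] + jitter[:, 0], idx_c[pick] + jitter[:, 1]], axis=1)


def generate_slide(spec: PhantomSpec) -> tuple[SlideImage, AnnotationSet, PhantomTruth]:
    """Render one phantom slide with its annotations and exact truth."""
    h, w = spec.canvas_height, spec.canvas_width
    rng = np.random.default_rng(spec.seed)

    # --- geometry: curved strip, tumour band, contingent split ----------
    phase = rng.uniform(0, 2 * np.pi)
    xs = np.linspace(spec.strip_margin, w - spec.strip_margin, 80)
    ys = h / 2 + spec.strip_amplitude * np.sin(2 * np.pi * xs / w + phase)
    strip = LineString(np.stack([xs, ys], axis=1)).buffer(spec.strip_width / 2)
    tissue_poly = strip.intersection(box(0, 0, w, h))
    if tissue_poly.is_empty:
        raise ValueError("infeasible geometry: tissue strip misses the canvas")
    tissue_mask = _rasterise(tissue_poly, h, w)
    n_tissue = int(tissue_mask.sum())

    target_tumour = spec.tumour_fraction_of_tissue * n_tissue
    max_start = max(int((1.0 - spec.tumour_fraction_of_tissue) * w * 0.5), 1)
    x0 = int(rng.integers(0, max_start))
    x1 = _column_cut(tissue_mask, x0, target_tumour)
    tumour_poly = tissue_poly.intersection(box(x0, -1, x1, h + 1))
    tumour_mask = _rasterise(tumour_poly, h, w) & tissue_mask
    n_tumour = int(tumour_mask.sum())
    if n_tumour == 0 and spec.tumour_fraction_of_tissue > 0:
        raise ValueError("infeasible geometry: empty tumour region")

    if spec.interleaved_mixing:
        # checkerboard split of the tumour area (stress mode)
        cols, rows = _pixel_centres(h, w)
        cell = 32
        board = ((rows // cell + cols // cell) % 2 == 0)
        a_mask = tumour_mask & board
        realised = a_mask.sum() / max(n_tumour, 1)
        # adjust roughly toward the requested fraction by column trimming
        if spec.contingent_fraction_A <= realised:
            xa = _column_cut(a_mask, 0, spec.contingent_fraction_A * n_tumour)
            a_mask[:, xa:] = False
        else:
            deficit = spec.contingent_fraction_A * n_tumour - a_mask.sum()
            extra = tumour_mask & ~board
            xa = _column_cut(extra, 0, deficit)
            a_mask |= extra & (np.arange(w)[None, :] < xa)
    else:
        xa = _column_cut(tumour_mask, x0, spec.contingent_fraction_A * n_tumour)
        if spec.contingent_fraction_A >= 1.0:
            a_mask = tumour_mask.copy()
        elif spec.contingent_fraction_A <= 0.0:
            a_mask = np.zeros_like(tumour_mask)
        else:
            a_mask = tumour_mask & (np.arange(w)[None, :] < xa)
    b_mask = tumour_mask & ~a_mask

    class_map = np.zeros((h, w), dtype=np.uint8)
    class_map[tissue_mask] = NON_TUMOUR
    class_map[a_mask] = TEXTURE_A
    class_map[b_mask] = TEXTURE_B

    # --- rendering ------------------------------------------------------
    canvas = np.empty((h, w, 3))
    canvas[:] = _BG

    nt_mask = tissue_mask & ~tumour_mask
    canvas[nt_mask] = _NON_TUMOUR_BASE
    for r, c in _scatter_positions(rng, nt_mask, spacing=9.0):
        _paint_disk(canvas, nt_mask, r, c, 1.2, _A_NUCLEUS * 0.6 + _NON_TUMOUR_BASE * 0.4)

    canvas[a_mask] = _A_BASE
    for r, c in _scatter_positions(rng, a_mask, spacing=2 * spec.cell_radius):
        shade = _A_CELL + rng.normal(0, 6, size=3)
        _paint_disk(canvas, a_mask, r, c, spec.cell_radius * rng.uniform(0.8, 1.2), shade)
        _paint_disk(canvas, a_mask, r, c, 1.2, _A_NUCLEUS)

    if b_mask.any():
        cols, rows = _pixel_centres(h, w)
        stripes = 0.5 + 0.5 * np.sin(2 * np.pi * (rows + 0.7 * cols) / spec.stroma_band_period)
        stroma = _B_STROMA[None, None, :] * (0.82 + 0.18 * stripes[..., None])
        canvas[b_mask] = stroma[b_mask]
        for r, c in _scatter_positions(rng, b_mask, spacing=2.6 * spec.ring_radius):
            _paint_ring(
                canvas, b_mask, r, c,
                spec.ring_radius * rng.uniform(0.8, 1.2), spec.ring_thickness,
                _B_RING + rng.normal(0, 5, size=3), _B_LUMEN,
            )

    canvas += rng.normal(0, spec.noise_level, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    slide = SlideImage(
        slide_id=spec.slide_id,
        pixel_array=pixels,
        microns_per_pixel=spec.microns_per_pixel,
    )

    polygons = []
    geoms = (
        list(tumour_poly.geoms) if isinstance(tumour_poly, MultiPolygon) else [tumour_poly]
    )
    for g in geoms:
        if isinstance(g, Polygon) and g.area > 0:
            polygons.append(np.asarray(g.exterior.coords))
    ann = AnnotationSet(slide_id=spec.slide_id, tumour_polygons=polygons)

    truth = PhantomTruth(
        tissue_mask=tissue_mask,
        tumour_mask=tumour_mask,
        class_map=class_map,
        contingent_fraction_A=float(a_mask.sum() / n_tumour) if n_tumour else float("nan"),
    )
    return slide, ann, truth


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass
class CohortData:
    """An in-memory phantom cohort mirroring the real-data interfaces."""

    slides: dict[str, SlideImage]
    annotations: dict[str, AnnotationSet]
    truths: dict[str, PhantomTruth]
    manifest: pd.DataFrame  # slide_id, diagnosis, split, true_fraction_A, mpp
    ihc_counts: pd.DataFrame  # slide_id + cell counts

    @property
    def split(self) -> dict[str, str]:
        return dict(zip(self.manifest["slide_id"], self.manifest["split"]))


def _stratified_split(ids: list[str], ratio: float, rng) -> dict[str, str]:
    n = len(ids)
    if n == 0:
        return {}
    n_train = int(round(ratio * n))
    if 0.0 < ratio < 1.0:
        if n < 2:
            raise ValueError(
                "cannot split a single-slide class across both partitions"
            )
        n_train = min(max(n_train, 1), n - 1)
    order = rng.permutation(n)
    return {
        ids[i]: ("train" if rank < n_train else "validation")
        for rank, i in enumerate(order)
    }


def generate_cohort(
    n_A_pure: int = 10,
    n_B_pure: int = 10,
    n_mixed: int = 10,
    mixed_fraction_range: tuple[float, float] = (0.2, 0.8),
    split_ratio: float = 0.7,
    seed: int = 0,
    ihc_cells: int = 1000,
    ihc_jitter: float = 0.05,
    spec_overrides: dict | None = None,
) -> CohortData:
    """Generate a balanced phantom cohort with truth tables and IHC counts.

    Pure texture-A slides carry an HCC label, pure texture-B slides iCCA,
    and mixed slides (contingent fraction drawn from
    ``mixed_fraction_range``) cHCC-CCA.  Synthetic IHC counts are binomial
    draws whose positive-cell probabilities track the true contingent
    fraction up to ``ihc_jitter`` of systematic noise.  The train /
    validation split is patient-level and stratified per diagnosis.
    """
    rng = np.random.default_rng(seed)
    overrides = spec_overrides or {}
    plan: list[tuple[str, float, Diagnosis]] = []
    for i in range(n_A_pure):
        plan.append((f"hcc_{i:02d}", 1.0, Diagnosis.HCC))
    for i in range(n_B_pure):
        plan.append((f"icca_{i:02d}", 0.0, Diagnosis.ICCA))
    for i in range(n_mixed):
        frac = float(rng.uniform(*mixed_fraction_range))
        plan.append((f"mixed_{i:02d}", frac, Diagnosis.CHCC_CCA))

    slides: dict[str, SlideImage] = {}
    annotations: dict[str, AnnotationSet] = {}
    truths: dict[str, PhantomTruth] = {}
    rows = []
    ihc_rows = []
    split: dict[str, str] = {}
    for diag in (Diagnosis.HCC, Diagnosis.ICCA, Diagnosis.CHCC_CCA):
        ids = [sid for sid, _, d in plan if d is diag]
        split.update(_stratified_split(ids, split_ratio, rng))

    for sid, frac_a, diag in plan:
        spec = PhantomSpec(
            slide_id=sid,
            contingent_fraction_A=frac_a,
            seed=int(rng.integers(0, 2**31 - 1)),
            **overrides,
        )
        slide, ann, truth = generate_slide(spec)
        slide.diagnosis_label = diag
        slides[sid] = slide
        annotations[sid] = ann
        truths[sid] = truth
        rows.append(
            {
                "slide_id": sid,
                "diagnosis": diag.value,
                "split": split[sid],
                "true_fraction_A": truth.contingent_fraction_A,
                "microns_per_pixel": spec.microns_per_pixel,
            }
        )
        n_cells = int(rng.integers(int(0.8 * ihc_cells), int(1.2 * ihc_cells) + 1))
        a = truth.contingent_fraction_A
        p_gly = float(np.clip(a + rng.uniform(-ihc_jitter, ihc_jitter), 0, 1))
        p_hep = float(np.clip(a + rng.uniform(-ihc_jitter, ihc_jitter), 0, 1))
        p_ck7 = float(np.clip((1 - a) + rng.uniform(-ihc_jitter, ihc_jitter), 0, 1))
        ihc_rows.append(
            {
                "slide_id": sid,
                "n_tumour_cells": n_cells,
                "n_positive_glypican3": int(rng.binomial(n_cells, p_gly)),
                "n_positive_hepatocyte": int(rng.binomial(n_cells, p_hep)),
                "n_positive_ck7": int(rng.binomial(n_cells, p_ck7)),
            }
        )

    return CohortData(
        slides=slides,
        annotations=annotations,
        truths=truths,
        manifest=pd.DataFrame(rows),
        ihc_counts=pd.DataFrame(ihc_rows),
    )


def write_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    """Persist a cohort in the real-data interchange formats.

    Slide PNGs, per-slide GeoJSON annotations, manifest and IHC CSVs, and
    truth-only files (class-map PNG + truth CSV) under ``truth/``.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for sid, slide in cohort.slides.items():
        p = out / "slides" / f"{sid}.png"
        iio.imwrite(p, slide.pixel_array)
        paths.append(str(p))
        ann = cohort.annotations[sid]
        features = [
            {
                "type": "Feature",
                "properties": {"classification": "tumour"},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [np.asarray(poly).tolist()],
                },
            }
            for poly in ann.tumour_polygons
        ]
        (out / "annotations" / f"{sid}.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )
        truth = cohort.truths[sid]
        iio.imwrite(out / "truth" / f"{sid}_classmap.png", truth.class_map * 85)
    manifest["path"] = paths
    manifest.to_csv(out / "slides.csv", index=False)
    cohort.ihc_counts.to_csv(out / "ihc_counts.csv", index=False)
    truth_rows = [
        {"slide_id": sid, "true_fraction_A": t.contingent_fraction_A,
         "n_tissue_px": int(t.tissue_mask.sum()), "n_tumour_px": int(t.tumour_mask.sum())}
        for sid, t in cohort.truths.items()
    ]
    pd.DataFrame(truth_rows).to_csv(out / "truth" / "truth.csv", index=False)


def pixel_statistic_accuracy(
    tiles_a: list[Patch] | list[np.ndarray],
    tiles_b: list[Patch] | list[np.ndarray],
) -> float:
    """Accuracy of a nearest-class-mean-colour classifier on two tile sets.

    A deliberately crude baseline: each tile is summarised by its mean RGB
    colour and assigned to the nearer class centroid.  Used to certify
    that the two phantom textures are separable before any network is
    trained.
    """

    def _mean_colour(t) -> np.ndarray:
        arr = t.pixels if isinstance(t, Patch) else t
        return np.asarray(arr, dtype=float).reshape(-1, 3).mean(axis=0)

    xa = np.stack([_mean_colour(t) for t in tiles_a])
    xb = np.stack([_mean_colour(t) for t in tiles_b])
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    correct = int(
        (np.linalg.norm(xa - ca, axis=1) < np.linalg.norm(xa - cb, axis=1)).sum()
    ) + int((np.linalg.norm(xb - cb, axis=1) < np.linalg.norm(xb - ca, axis=1)).sum())
    return correct / (len(xa) + len(xb))
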