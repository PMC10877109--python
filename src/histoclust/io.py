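"""Readers and writers for the on-disk interchange formats.

Slides are plain or pyramidal-less TIFF / PNG rasters; annotations are
GeoJSON FeatureCollections of Polygon features named ``<slide_id>.geojson``;
manifests and IHC counts are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .slide_analysis import IHCCellCounts
from .tiling import AnnotationSet, Diagnosis, Patch, SlideImage

__all__ = [
    "load_slide_image",
    "load_annotation_geojson",
    "load_slide_manifest",
    "load_ihc_counts",
    "write_patches",
    "load_patches",
]


def load_slide_image(
    path: str | Path,
    slide_id: str,
    microns_per_pixel: float,
    diagnosis: str = "unknown",
) -> SlideImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    return SlideImage(
        slide_id=slide_id,
        pixel_array=np.asarray(arr, dtype=np.uint8),
        microns_per_pixel=microns_per_pixel,
        diagnosis_label=Diagnosis(diagnosis),
    )


def load_annotation_geojson(path: str | Path, slide_id: str) -> AnnotationSet:
    payload = json.loads(Path(path).read_text())
    polygons = []
    for feature in payload.get("features", []):
        geom = feature.get("geometry", {})
        if geom.get("type") == "Polygon":
            polygons.append(np.asarray(geom["coordinates"][0], dtype=float))
        elif geom.get("type") == "MultiPolygon":
            for part in geom["coordinates"]:
                polygons.append(np.asarray(part[0], dtype=float))
    return AnnotationSet(slide_id=slide_id, tumour_polygons=polygons)


def load_slide_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"slide_id", "path", "microns_per_pixel", "diagnosis"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"slide manifest missing columns: {sorted(missing)}")
    return df


def load_ihc_counts(path: str | Path) -> list[IHCCellCounts]:
    df = pd.read_csv(path)
    return [
        IHCCellCounts(
            slide_id=row.slide_id,
            n_tumour_cells=int(row.n_tumour_cells),
            n_positive_glypican3=int(row.n_positive_glypican3),
            n_positive_hepatocyte=int(row.n_positive_hepatocyte),
            n_positive_ck7=int(row.n_positive_ck7),
        )
        for row in df.itertuples()
    ]


def write_patches(patches: list[Patch], out_dir: str | Path) -> pd.DataFrame:
    """PNG tile per patch plus a manifest CSV; returns the manifest."""
    import imageio.v3 as iio

    from .tiling import patch_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = patch_manifest(patches)
    paths = []
    by_key = {p.key: p for p in patches}
    for row in manifest.itertuples():
        p = by_key[(row.slide_id, row.grid_row, row.grid_col)]
        name = f"{p.slide_id}_r{p.grid_row:03d}_c{p.grid_col:03d}.png"
        iio.imwrite(out / name, p.pixels)
        paths.append(name)
    manifest["patch_path"] = paths
    manifest.to_csv(out / "patches.csv", index=False)
    return manifest


def load_patches(tile_dir: str | Path) -> list[Patch]:
    import imageio.v3 as iio

    tile_dir = Path(tile_dir)
    manifest = pd.read_csv(tile_dir / "patches.csv")
    patches = []
    for row in manifest.itertuples():
        pixels = iio.imread(tile_dir / row.patch_path)
        patches.append(
            Patch(
                slide_id=row.slide_id,
                grid_row=int(row.grid_row),
                grid_col=int(row.grid_col),
                pixels=np.asarray(pixels, dtype=np.uint8),
                tissue_fraction=float(row.tissue_fraction),
                tumour_fraction=float(row.tumour_fraction),
            )
        )
    return patches
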