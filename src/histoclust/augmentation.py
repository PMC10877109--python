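"""Plausibility-restricted augmentation of histology tiles.

The transform family is deliberately narrow so augmented tiles remain
pathologically meaningful: small hue shifts, saturation / brightness
jitter, rigid flips and rotations, a mild 3x3 Gaussian blur and a small
scale jitter.  Transforms are composed in a fixed canonical order
(scale -> rotation -> flips -> colour -> blur) so a seed fully determines
the output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize, rotate

from .tiling import Patch

__all__ = ["AugmentationPolicy", "augment_patch", "build_training_set", "summarise_manifest"]

# Hard bounds of the plausible-transform family; wider ranges need an
# explicit opt-in (allow_custom_ranges).
_BOUNDS = {
    "hue_delta": 0.02,
    "saturation_scale": (0.2, 1.6),
    "brightness_delta": 0.2,
    "rotation_deg": 90.0,
    "scale_jitter": (1.0, 1.2),
}

# 3x3 Gaussian kernel (sigma ~ 0.85), normalised.
_BLUR_KERNEL = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0


@dataclass(frozen=True)
class AugmentationPolicy:
    """Sampling ranges for the augmentation transforms.

    Defaults are the plausible-transform bounds: +/-2% hue, -80%..+60%
    multiplicative saturation, +/-20% brightness, rotations in
    [-90, +90] degrees, independent horizontal/vertical flips, optional
    3x3 Gaussian blur, and a scale jitter in [1.0, 1.2].
    """

    hue_delta: float = 0.02
    saturation_scale: tuple[float, float] = (0.2, 1.6)
    brightness_delta: float = 0.2
    rotation_deg: float = 90.0
    hflip: bool = True
    vflip: bool = True
    blur_prob: float = 0.25
    scale_jitter: tuple[float, float] = (1.0, 1.2)
    n_augments_per_patch: int = 1
    seed: int = 0
    allow_custom_ranges: bool = False

    def __post_init__(self) -> None:
        if self.n_augments_per_patch < 0:
            raise ValueError("n_augments_per_patch must be >= 0")
        if not 0.0 <= self.blur_prob <= 1.0:
            raise ValueError("blur_prob must be in [0, 1]")
        if self.allow_custom_ranges:
            return
        if abs(self.hue_delta) > _BOUNDS["hue_delta"] + 1e-12:
            raise ValueError("hue_delta outside the plausible range (+/-0.02)")
        lo, hi = self.saturation_scale
        blo, bhi = _BOUNDS["saturation_scale"]
        if lo < blo - 1e-12 or hi > bhi + 1e-12 or lo > hi:
            raise ValueError("saturation_scale outside the plausible range [0.2, 1.6]")
        if abs(self.brightness_delta) > _BOUNDS["brightness_delta"] + 1e-12:
            raise ValueError("brightness_delta outside the plausible range (+/-0.2)")
        if abs(self.rotation_deg) > _BOUNDS["rotation_deg"] + 1e-12:
            raise ValueError("rotation_deg outside the plausible range (+/-90)")
        slo, shi = self.scale_jitter
        blo, bhi = _BOUNDS["scale_jitter"]
        if slo < blo - 1e-12 or shi > bhi + 1e-12 or slo > shi:
            raise ValueError("scale_jitter outside the plausible range [1.0, 1.2]")


def sample_parameters(policy: AugmentationPolicy, draw: np.random.Generator) -> dict:
    """Draw one set of transform parameters from the policy ranges."""
    return {
        "scale": float(draw.uniform(*policy.scale_jitter)),
        "angle": float(draw.uniform(-policy.rotation_deg, policy.rotation_deg)),
        "hflip": bool(policy.hflip and draw.random() < 0.5),
        "vflip": bool(policy.vflip and draw.random() < 0.5),
        "hue": float(draw.uniform(-policy.hue_delta, policy.hue_delta)),
        "saturation": float(draw.uniform(*policy.saturation_scale)),
        "brightness": float(draw.uniform(-policy.brightness_delta, policy.brightness_delta)),
        "blur": bool(draw.random() < policy.blur_prob),
    }


def _apply_transform(pixels: np.ndarray, p: dict) -> np.ndarray:
    img = pixels.astype(float) / 255.0
    size = img.shape[0]
    if p["scale"] != 1.0:
        big = int(round(size * p["scale"]))
        img = resize(img, (big, big, 3), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
        off = (big - size) // 2
        img = img[off : off + size, off : off + size]
    if p["angle"] != 0.0:
        img = rotate(img, p["angle"], mode="reflect", order=1, preserve_range=True)
    if p["hflip"]:
        img = img[:, ::-1]
    if p["vflip"]:
        img = img[::-1, :]
    if p["hue"] != 0.0 or p["saturation"] != 1.0 or p["brightness"] != 0.0:
        hsv = rgb2hsv(np.clip(img, 0, 1))
        hsv[..., 0] = np.mod(hsv[..., 0] + p["hue"], 1.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * p["saturation"], 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] + p["brightness"], 0, 1)
        img = hsv2rgb(hsv)
    if p["blur"]:
        img = np.stack(
            [convolve(img[..., c], _BLUR_KERNEL, mode="reflect") for c in range(3)],
            axis=-1,
        )
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def augment_patch(
    patch: Patch,
    policy: AugmentationPolicy,
    draw: np.random.Generator,
) -> tuple[Patch, dict]:
    """Return an augmented copy of ``patch`` and the sampled parameters.

    Identity policies (all ranges collapsed, no flips/blur) return the
    pixels unchanged; labels and provenance are always preserved.
    """
    params = sample_parameters(policy, draw)
    identity = (
        params["scale"] == 1.0
        and params["angle"] == 0.0
        and not params["hflip"]
        and not params["vflip"]
        and params["hue"] == 0.0
        and params["saturation"] == 1.0
        and params["brightness"] == 0.0
        and not params["blur"]
    )
    pixels = patch.pixels.copy() if identity else _apply_transform(patch.pixels, params)
    return replace(patch, pixels=pixels), params


def build_training_set(
    patches: Sequence[Patch],
    policy: AugmentationPolicy,
    split: dict[str, str],
) -> tuple[list[Patch], list[Patch], pd.DataFrame]:
    """Assemble train/validation tiles with a patient-level split.

    ``split`` maps every slide_id to ``"train"`` or ``"validation"``.
    Training tiles are the originals plus ``n_augments_per_patch``
    augmented copies of each; validation tiles are never augmented.
    Returns (train_tiles, validation_tiles, manifest); the manifest logs
    each tile's provenance and sampled transform parameters.
    """
    for sid, part in split.items():
        if part not in ("train", "validation"):
            raise ValueError(f"slide {sid!r}: split must be 'train' or 'validation', got {part!r}")
    rng = np.random.default_rng(policy.seed)
    train: list[Patch] = []
    val: list[Patch] = []
    rows = []
    for patch in patches:
        part = split.get(patch.slide_id)
        if part is None:
            raise ValueError(f"slide {patch.slide_id!r} missing from the split")
        if part == "validation":
            val.append(patch)
            rows.append(_manifest_row(patch, "validation", "original", None))
            continue
        train.append(patch)
        rows.append(_manifest_row(patch, "train", "original", None))
        for k in range(policy.n_augments_per_patch):
            aug, params = augment_patch(patch, policy, rng)
            train.append(aug)
            rows.append(_manifest_row(aug, "train", f"augment_{k}", params))
    manifest = pd.DataFrame(
        rows,
        columns=["slide_id", "grid_row", "grid_col", "weak_label", "split",
                 "provenance", "transform_params"],
    )
    return train, val, manifest


def _manifest_row(patch: Patch, split: str, provenance: str, params: dict | None) -> dict:
    return {
        "slide_id": patch.slide_id,
        "grid_row": patch.grid_row,
        "grid_col": patch.grid_col,
        "weak_label": patch.weak_label,
        "split": split,
        "provenance": provenance,
        "transform_params": "" if params is None else repr(params),
    }


def summarise_manifest(manifest: pd.DataFrame) -> dict:
    """Tile counts per partition plus the grand total."""
    n_train = int((manifest["split"] == "train").sum())
    n_val = int((manifest["split"] == "validation").sum())
    return {"n_train": n_train, "n_validation": n_val, "n_total": n_train + n_val}


def check_patient_level_split(split_assignments: Sequence[tuple[str, str]]) -> dict[str, str]:
    """Validate that no slide appears in both partitions; return the mapping."""
    mapping: dict[str, str] = {}
    for sid, part in split_assignments:
        if sid in mapping and mapping[sid] != part:
            raise ValueError(f"patient leakage: slide {sid!r} assigned to both partitions")
        mapping[sid] = part
    return mapping
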