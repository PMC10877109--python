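"""Shared fixtures: tiny phantom cohorts and synthetic tiles."""

from __future__ import annotations

import numpy as np
import pytest

from histoclust.phantom import PhantomSpec, generate_cohort, generate_slide
from histoclust.tiling import Patch


@pytest.fixture(scope="session")
def mini_cohort():
    """A 3+3+3 phantom cohort shared across read-only tests."""
    return generate_cohort(3, 3, 3, seed=7)


@pytest.fixture(scope="session")
def phantom_half():
    """One phantom slide with a 50/50 contingent split."""
    spec = PhantomSpec(slide_id="half", contingent_fraction_A=0.5, seed=11)
    return generate_slide(spec)


def make_tile(rng: np.random.Generator, base: tuple[int, int, int], size: int = 32,
              speckle: float = 20.0) -> np.ndarray:
    """A noisy constant-colour tile with a little texture."""
    arr = np.full((size, size, 3), base, dtype=float)
    arr += rng.normal(0, speckle, size=arr.shape)
    return np.clip(arr, 0, 255).astype(np.uint8)


def make_patch(pixels: np.ndarray, slide_id: str = "s", grid_row: int = 0,
               grid_col: int = 0, tumour: bool = False) -> Patch:
    return Patch(
        slide_id=slide_id,
        grid_row=grid_row,
        grid_col=grid_col,
        pixels=pixels,
        tissue_fraction=1.0,
        tumour_fraction=1.0 if tumour else 0.0,
    )


@pytest.fixture()
def tile_factory():
    return make_tile


@pytest.fixture()
def patch_factory():
    return make_patch


@pytest.fixture(scope="session")
def toy_training_patches():
    """Balanced, trivially separable tumour / non-tumour 32px tiles."""
    rng = np.random.default_rng(5)
    patches = []
    for i in range(40):
        tumour = i % 2 == 0
        base = (200, 80, 120) if tumour else (240, 220, 225)
        patches.append(
            make_patch(make_tile(rng, base), slide_id=f"train_{i % 8}",
                       grid_row=i // 8, grid_col=i % 8, tumour=tumour)
        )
    return patches
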