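"""Tile one annotated phantom slide into weakly labelled patches.

Builds a 50/50 mixed phantom, masks the background, rasterises the
tumour annotation polygons and extracts the 125 um / 64 px patch grid.
"""

from histoclust.phantom import PhantomSpec, generate_slide
from histoclust.tiling import (
    compute_tissue_mask,
    extract_patches,
    patch_manifest,
    rasterise_annotations,
)

slide, annotations, truth = generate_slide(
    PhantomSpec(slide_id="demo", contingent_fraction_A=0.5, seed=3)
)
tissue = compute_tissue_mask(slide)
tumour = rasterise_annotations(slide, annotations)
patches = extract_patches(slide, tissue, tumour, patch_microns=125, patch_pixels=64)

manifest = patch_manifest(patches)
print(manifest.to_string(index=False))
n_tumour = (manifest.weak_label == "tumour").sum()
print(f"\n{len(patches)} tissue patches retained; {n_tumour} carry the weak tumour label")
print("(a patch is 'tumour' when >50% of its window lies inside the annotation)")
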