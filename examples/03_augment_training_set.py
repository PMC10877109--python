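"""Expand training tiles with the plausibility-restricted transforms.

Shows the augmentation policy ranges, builds a patient-level train /
validation set with 2 augmented copies per training tile, and prints the
tile accounting.
"""

from histoclust.augmentation import AugmentationPolicy, build_training_set, summarise_manifest
from histoclust.phantom import generate_cohort
from histoclust.pipeline import tile_cohort

cohort = generate_cohort(2, 2, 2, seed=5)
patches = [p for tiles in tile_cohort(cohort).values() for p in tiles]

policy = AugmentationPolicy(n_augments_per_patch=2, seed=17)
train, val, manifest = build_training_set(patches, policy, cohort.split)

print(f"policy: hue +/-{policy.hue_delta}, saturation x{policy.saturation_scale}, "
      f"brightness +/-{policy.brightness_delta}, rotation +/-{policy.rotation_deg} deg, "
      f"blur p={policy.blur_prob}, scale {policy.scale_jitter}")
print(summarise_manifest(manifest))
print("training tiles = originals x (1 + n_augments); validation tiles are never augmented")
print(manifest.head(6).to_string(index=False))
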