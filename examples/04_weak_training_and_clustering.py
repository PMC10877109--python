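"""Weak training, feature extraction, PCA halving and GMM clustering.

Trains the compact tumour/non-tumour classifier on a small phantom
cohort, extracts last-conv-layer features for validation tumour tiles,
halves them with PCA and fits a two-component Gaussian mixture.
"""

import numpy as np

from histoclust.augmentation import AugmentationPolicy, build_training_set
from histoclust.clustering import assign_clusters, fit_gmm, map_clusters_to_types, reduce_pca
from histoclust.learning import BackboneConfig, extract_features, train_weak_classifier
from histoclust.phantom import generate_cohort
from histoclust.pipeline import tile_cohort

cohort = generate_cohort(4, 4, 4, seed=11)
patches = [p for tiles in tile_cohort(cohort).values() for p in tiles]
policy = AugmentationPolicy(n_augments_per_patch=1, seed=11)
train, val, _ = build_training_set(patches, policy, cohort.split)

config = BackboneConfig(seed=11, epochs=5, learning_rate=0.003)
model, report = train_weak_classifier(train, val, config)
print(f"weak classifier: train acc {report.train_accuracy:.2f}, "
      f"validation acc {report.val_accuracy:.2f}")
print(f"learning rates per epoch: {[f'{lr:.4g}' for lr in report.learning_rates]}")

val_tumour = [p for p in val if p.weak_label == "tumour"]
features = extract_features(model, val_tumour)
matrix = np.stack([f.pooled_vector for f in features])
reduced, reducer = reduce_pca(matrix)  # 32 -> 16 dims
print(f"\nfeatures: {matrix.shape} -> PCA -> {reduced.shape}")

mixture = fit_gmm(reduced, K=2, seed=11)
print(f"mixture weights: {np.round(mixture.weights, 3)} "
      f"(components ordered by weight; EM iterations: {mixture.n_iter})")

assignments = assign_clusters(mixture, reduced, keys=[f.key for f in features])
diagnosis = dict(zip(cohort.manifest.slide_id, cohort.manifest.diagnosis))
reference = {p.key: diagnosis[p.slide_id] for p in val_tumour
             if diagnosis[p.slide_id] in ("HCC", "iCCA")}
mapping, composition = map_clusters_to_types(assignments, reference)
print(f"\ncluster -> tumour type map: {mapping}")
print(composition.to_string(index=False))
# pct_of_cluster is the share of each cluster's reference tiles carrying
# a given diagnosis: a clean split puts HCC-slide tiles in one cluster
# and iCCA-slide tiles in the other.
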