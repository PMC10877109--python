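"""End-to-end orchestration of the weakly supervised clustering pipeline.

``run_cohort_pipeline`` takes a phantom cohort (or any in-memory cohort in
the same shape) through the full method: tiling with tissue masking,
patient-level split with augmentation, weak tumour/non-tumour training,
last-conv feature extraction of tumour tiles, PCA halving, Gaussian
mixture clustering, cluster-to-type mapping on pure-diagnosis reference
slides, and slide-level contingent reports with agreement and IHC
correlation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augmentation import AugmentationPolicy, build_training_set
from .clustering import (
    ClusterAssignment,
    MixtureModel,
    PCAReducer,
    assign_clusters,
    fit_gmm,
    map_clusters_to_types,
    reduce_pca,
)
from .learning import BackboneConfig, TrainingReport, extract_features, train_weak_classifier
from .nn import SmallCNN
from .phantom import CohortData
from .slide_analysis import (
    SlideReport,
    compute_slide_proportions,
    ihc_contingents,
    predict_major_contingent,
)
from .tiling import Diagnosis, Patch, compute_tissue_mask, extract_patches, rasterise_annotations

__all__ = ["PipelineResult", "run_cohort_pipeline", "tile_cohort"]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, from tiles to slide reports."""

    patches: dict[str, list[Patch]]
    model: SmallCNN
    training_report: TrainingReport
    reducer: PCAReducer
    mixture: MixtureModel
    cluster_type_map: dict[int, str]
    composition: pd.DataFrame
    assignments: list[ClusterAssignment]
    slide_reports: dict[str, SlideReport]
    metrics: dict[str, float] = field(default_factory=dict)


def tile_cohort(
    cohort: CohortData,
    patch_microns: float = 125.0,
    patch_pixels: int = 64,
    tissue_threshold: float = 0.5,
) -> dict[str, list[Patch]]:
    """Tissue-masked, weakly labelled patches for every cohort slide."""
    out: dict[str, list[Patch]] = {}
    for sid, slide in cohort.slides.items():
        tissue = compute_tissue_mask(slide)
        tumour = rasterise_annotations(slide, cohort.annotations[sid])
        out[sid] = extract_patches(
            slide,
            tissue,
            tumour,
            patch_microns=patch_microns,
            patch_pixels=patch_pixels,
            tissue_threshold=tissue_threshold,
        )
    return out


def run_cohort_pipeline(
    cohort: CohortData,
    config: BackboneConfig | None = None,
    k: int = 2,
    seed: int = 0,
    n_augments_per_patch: int = 1,
    patch_pixels: int = 64,
) -> PipelineResult:
    """Run the full weakly supervised clustering method on a cohort.

    The feature extractor is trained on the training partition
    (originals + augments); PCA and the K-component mixture are fitted on
    tumour tiles of the validation partition, then applied to tumour
    tiles of every slide for the per-slide reports.  Clusters are mapped
    to tumour types by majority vote over tiles from pure-diagnosis
    validation slides.
    """
    if config is None:
        # desk-scale defaults: the compact random-init backbone trains from
        # scratch and wants a smaller step than the transfer-learning recipe
        config = BackboneConfig(seed=seed, epochs=5, learning_rate=0.003)

    patches = tile_cohort(cohort, patch_pixels=patch_pixels)
    all_patches = [p for tiles in patches.values() for p in tiles]

    policy = AugmentationPolicy(n_augments_per_patch=n_augments_per_patch, seed=seed)
    train_tiles, val_tiles, _ = build_training_set(all_patches, policy, cohort.split)

    model, report = train_weak_classifier(train_tiles, val_tiles, config)

    diagnosis = dict(zip(cohort.manifest["slide_id"], cohort.manifest["diagnosis"]))
    split = cohort.split
    val_tumour = [p for p in val_tiles if p.weak_label == "tumour"]
    if not val_tumour:
        raise ValueError("no tumour tiles in the validation partition")

    feats = extract_features(model, val_tumour)
    matrix = np.stack([f.pooled_vector for f in feats])
    reduced, reducer = reduce_pca(matrix)
    mixture = fit_gmm(reduced, K=k, seed=seed)

    val_assign = assign_clusters(mixture, reduced, keys=[f.key for f in feats])
    reference = {
        p.key: diagnosis[p.slide_id]
        for p in val_tumour
        if diagnosis[p.slide_id] in (Diagnosis.HCC.value, Diagnosis.ICCA.value)
    }
    cluster_type_map, composition = map_clusters_to_types(val_assign, reference)

    # apply the fitted extractor/reducer/mixture to every slide's tumour tiles
    all_tumour = [p for p in all_patches if p.weak_label == "tumour"]
    all_feats = extract_features(model, all_tumour)
    all_reduced = reducer.transform(np.stack([f.pooled_vector for f in all_feats]))
    assignments = assign_clusters(mixture, all_reduced, keys=[f.key for f in all_feats])

    ihc = {
        row.slide_id: row for row in cohort.ihc_counts.itertuples()
    } if len(cohort.ihc_counts) else {}
    reports: dict[str, SlideReport] = {}
    for sid in cohort.slides:
        if not any(a.slide_id == sid for a in assignments):
            continue
        rep = compute_slide_proportions(assignments, sid, K=k)
        rep.pathology_diagnosis = diagnosis[sid]
        rep.predicted_major_contingent = predict_major_contingent(rep, cluster_type_map)
        if sid in ihc:
            row = ihc[sid]
            from .slide_analysis import IHCCellCounts

            hcc_pct, icca_pct = ihc_contingents(
                IHCCellCounts(
                    slide_id=sid,
                    n_tumour_cells=int(row.n_tumour_cells),
                    n_positive_glypican3=int(row.n_positive_glypican3),
                    n_positive_hepatocyte=int(row.n_positive_hepatocyte),
                    n_positive_ck7=int(row.n_positive_ck7),
                )
            )
            rep.ihc_hcc_contingent_pct = hcc_pct
            rep.ihc_icca_contingent_pct = icca_pct
        reports[sid] = rep

    metrics = _evaluate(cohort, reports, cluster_type_map, report)
    return PipelineResult(
        patches=patches,
        model=model,
        training_report=report,
        reducer=reducer,
        mixture=mixture,
        cluster_type_map=cluster_type_map,
        composition=composition,
        assignments=assignments,
        slide_reports=reports,
        metrics=metrics,
    )


def _evaluate(
    cohort: CohortData,
    reports: dict[str, SlideReport],
    cluster_type_map: dict[int, str],
    training_report: TrainingReport,
) -> dict[str, float]:
    truth = {
        row.slide_id: (row.diagnosis, row.true_fraction_A)
        for row in cohort.manifest.itertuples()
    }
    hcc_clusters = [c for c, t in cluster_type_map.items() if t == Diagnosis.HCC.value]

    pure_total = pure_correct = 0
    mixed_pred, mixed_true = [], []
    for sid, rep in reports.items():
        diag, frac_a = truth[sid]
        if diag in (Diagnosis.HCC.value, Diagnosis.ICCA.value):
            pure_total += 1
            pure_correct += int(rep.predicted_major_contingent == diag)
        else:
            pred_a = float(sum(rep.proportion_per_cluster[c] for c in hcc_clusters))
            mixed_pred.append(pred_a)
            mixed_true.append(frac_a)

    metrics = {
        "weak_classifier_val_accuracy": training_report.val_accuracy,
        "pure_slide_accuracy": pure_correct / pure_total if pure_total else float("nan"),
    }
    if len(mixed_true) >= 3 and np.std(mixed_true) > 0 and np.std(mixed_pred) > 0:
        metrics["mixed_fraction_pearson_r"] = float(
            np.corrcoef(mixed_pred, mixed_true)[0, 1]
        )
    icca_clusters = [c for c, t in cluster_type_map.items() if t == Diagnosis.ICCA.value]
    with_ihc = [
        r for r in reports.values()
        if r.ihc_hcc_contingent_pct is not None and r.ihc_icca_contingent_pct is not None
    ]
    if hcc_clusters and icca_clusters and len(with_ihc) >= 3:
        from .slide_analysis import proportion_ihc_correlation

        r_hcc, r_icca = proportion_ihc_correlation(
            with_ihc, hcc_cluster=hcc_clusters[0], icca_cluster=icca_clusters[0]
        )
        metrics["ihc_pearson_r_hcc"] = r_hcc
        metrics["ihc_pearson_r_icca"] = r_icca
    return metrics
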