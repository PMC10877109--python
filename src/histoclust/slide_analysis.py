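"""Slide-level aggregation: contingent proportions, diagnosis, agreement.

Tile-level cluster assignments are aggregated into per-slide cluster
proportions; the slide's predicted "major contingent" is the tumour type
of the dominant cluster (same-type clusters are pooled first).  Agreement
with the pathology diagnosis is tabulated per diagnosis group, and the
model's contingent proportions are correlated (Pearson) with contingents
quantified from immunohistochemistry cell counts.

The IHC rule: the HCC contingent percentage is the larger of the
glypican-3 and anti-hepatocyte positive-cell ratios; the iCCA contingent
percentage is the CK7 positive-cell ratio.

Printed percentages use round-half-up to the nearest integer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment

__all__ = [
    "SlideReport",
    "IHCCellCounts",
    "AgreementTable",
    "round_half_up",
    "compute_slide_proportions",
    "predict_major_contingent",
    "ihc_contingents",
    "diagnostic_agreement",
    "proportion_ihc_correlation",
]

INDETERMINATE = "indeterminate"


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(np.floor(x + 0.5))


@dataclass
class SlideReport:
    """Per-slide summary of the clustered tumour tiles."""

    slide_id: str
    n_tumour_tiles: int = 0
    proportion_per_cluster: np.ndarray = field(default_factory=lambda: np.array([]))
    tiles_per_cluster: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    predicted_major_contingent: str | None = None
    pathology_diagnosis: str | None = None
    ihc_hcc_contingent_pct: float | None = None
    ihc_icca_contingent_pct: float | None = None


@dataclass
class IHCCellCounts:
    """Positive-cell counts for the three routine liver-cancer markers."""

    slide_id: str
    n_tumour_cells: int
    n_positive_glypican3: int
    n_positive_hepatocyte: int
    n_positive_ck7: int

    def __post_init__(self) -> None:
        if self.n_tumour_cells <= 0:
            raise ValueError(f"slide {self.slide_id!r}: n_tumour_cells must be > 0")
        for name in ("n_positive_glypican3", "n_positive_hepatocyte", "n_positive_ck7"):
            v = getattr(self, name)
            if v < 0 or v > self.n_tumour_cells:
                raise ValueError(
                    f"slide {self.slide_id!r}: {name}={v} outside [0, n_tumour_cells]"
                )


@dataclass
class AgreementTable:
    """Per-diagnosis-group concordance between pathology and model."""

    per_group: pd.DataFrame  # diagnosis, n_cases, n_concordant, agreement_pct, fraction

    def agreement_pct(self, diagnosis: str) -> int:
        row = self.per_group[self.per_group["diagnosis"] == diagnosis]
        if row.empty:
            raise KeyError(f"no cases with diagnosis {diagnosis!r}")
        return int(row["agreement_pct"].iloc[0])


def compute_slide_proportions(
    assignments: Sequence[ClusterAssignment],
    slide_id: str,
    K: int | None = None,
) -> SlideReport:
    """Fraction of the slide's tumour tiles falling in each cluster."""
    mine = [a for a in assignments if a.slide_id == slide_id]
    if not mine:
        raise ValueError(f"slide {slide_id!r} has no tumour-tile assignments")
    if K is None:
        K = len(mine[0].responsibilities)
    counts = np.zeros(K, dtype=int)
    for a in mine:
        counts[a.cluster_id] += 1
    return SlideReport(
        slide_id=slide_id,
        n_tumour_tiles=len(mine),
        tiles_per_cluster=counts,
        proportion_per_cluster=counts / len(mine),
    )


def predict_major_contingent(
    report: SlideReport,
    cluster_type_map: dict[int, str],
) -> str:
    """Tumour type of the dominant contingent; ties are flagged.

    Same-type clusters are pooled before the argmax (relevant when two
    clusters both map to HCC).  An exact tie between two different types
    returns the ``indeterminate`` flag rather than silently breaking it.
    """
    props = report.proportion_per_cluster
    if props.size == 0:
        raise ValueError(f"slide {report.slide_id!r}: proportions not computed")
    by_type: dict[str, float] = {}
    for cid, p in enumerate(props):
        if cid not in cluster_type_map:
            raise KeyError(f"cluster {cid} missing from the cluster->type map")
        by_type[cluster_type_map[cid]] = by_type.get(cluster_type_map[cid], 0.0) + float(p)
    best = max(by_type.values())
    winners = sorted(t for t, v in by_type.items() if abs(v - best) < 1e-12)
    if len(winners) > 1:
        return INDETERMINATE
    return winners[0]


def ihc_contingents(counts: IHCCellCounts) -> tuple[float, float]:
    """(hcc_pct, icca_pct) from marker-positive cell ratios.

    hcc_pct = 100 * max(glypican3, hepatocyte) / tumour cells;
    icca_pct = 100 * CK7 / tumour cells.
    """
    n = counts.n_tumour_cells
    hcc = 100.0 * max(counts.n_positive_glypican3, counts.n_positive_hepatocyte) / n
    icca = 100.0 * counts.n_positive_ck7 / n
    return hcc, icca


def diagnostic_agreement(
    cases: Sequence[tuple[str, str]],
    concordant_fn=None,
) -> AgreementTable:
    """Concordance between pathology diagnosis and predicted contingent.

    ``cases`` is a list of (pathology_diagnosis, predicted_major_contingent).
    By default a case is concordant when the two labels are equal; for
    combined-tumour (cHCC-CCA) cases the pathology column should carry the
    pathologist's major contingent so equality remains the right test, or
    pass ``concordant_fn(diagnosis, predicted) -> bool`` to customise.
    Percentages are rounded half-up; raw fractions are retained.
    """
    if concordant_fn is None:
        concordant_fn = lambda d, p: d == p  # noqa: E731
    groups: dict[str, list[bool]] = {}
    for diagnosis, predicted in cases:
        groups.setdefault(diagnosis, []).append(bool(concordant_fn(diagnosis, predicted)))
    rows = []
    for diagnosis in sorted(groups):
        outcomes = groups[diagnosis]
        n = len(outcomes)
        if n == 0:
            warnings.warn(f"empty diagnosis group {diagnosis!r} omitted", stacklevel=2)
            continue
        c = int(sum(outcomes))
        rows.append(
            {
                "diagnosis": diagnosis,
                "n_cases": n,
                "n_concordant": c,
                "fraction": c / n,
                "agreement_pct": round_half_up(100.0 * c / n),
            }
        )
    return AgreementTable(per_group=pd.DataFrame(rows))


def proportion_ihc_correlation(
    reports: Sequence[SlideReport],
    hcc_cluster: int = 0,
    icca_cluster: int = 1,
) -> tuple[float, float]:
    """Pearson r of model cluster proportions against IHC contingents.

    Returns (r for HCC-cluster proportion vs hcc_pct, r for iCCA-cluster
    proportion vs icca_pct) over slides that carry both quantities.
    Requires at least 3 such slides and non-zero variance in each
    variable; a zero-variance pairing yields NaN with a warning.
    """
    paired = [
        r
        for r in reports
        if r.ihc_hcc_contingent_pct is not None
        and r.ihc_icca_contingent_pct is not None
        and r.proportion_per_cluster.size > max(hcc_cluster, icca_cluster)
    ]
    if len(paired) < 3:
        raise ValueError(f"need >= 3 slides with both model and IHC data, got {len(paired)}")

    def _pearson(x: np.ndarray, y: np.ndarray) -> float:
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn("zero variance: Pearson correlation undefined", stacklevel=3)
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    model_hcc = np.array([100.0 * r.proportion_per_cluster[hcc_cluster] for r in paired])
    model_icca = np.array([100.0 * r.proportion_per_cluster[icca_cluster] for r in paired])
    ihc_hcc = np.array([r.ihc_hcc_contingent_pct for r in paired])
    ihc_icca = np.array([r.ihc_icca_contingent_pct for r in paired])
    return _pearson(model_hcc, ihc_hcc), _pearson(model_icca, ihc_icca)
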