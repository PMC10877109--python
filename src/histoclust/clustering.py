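"""PCA reduction and Gaussian-mixture clustering of tile features.

Tumour-tile features are mean-centred, projected onto their top D/2
principal components, and clustered with a K-component Gaussian mixture
fitted by expectation-maximization.  The EM loop is implemented here
because the pipeline's contracts need the per-iteration log-likelihood
trace (monotonicity audit) and exact control of initialisation; k-means
provides the default initialisation, and the best of ``n_init`` seeded
restarts is kept.

Components are re-indexed by descending mixture weight after fitting so
"cluster 0 / cluster 1" is stable across runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .tiling import SlideImage

__all__ = [
    "PCAReducer",
    "reduce_pca",
    "MixtureModel",
    "ClusterAssignment",
    "fit_gmm",
    "em_step_loop",
    "assign_clusters",
    "map_clusters_to_types",
    "reconstruct_label_map",
]


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


@dataclass
class PCAReducer:
    """A fitted principal-component projection (mean + components)."""

    mean: np.ndarray  # (D,)
    components: np.ndarray  # (d, D)
    explained_variance: np.ndarray  # (d,)
    explained_variance_ratio: np.ndarray  # (d,)

    @property
    def target_dim(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match the fitted "
                f"transform ({self.mean.shape[0]})"
            )
        return (x - self.mean) @ self.components.T

    def save(self, path: str | Path) -> None:
        np.savez(
            Path(path),
            mean=self.mean,
            components=self.components,
            explained_variance=self.explained_variance,
            explained_variance_ratio=self.explained_variance_ratio,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAReducer":
        with np.load(Path(path)) as data:
            return cls(
                mean=data["mean"],
                components=data["components"],
                explained_variance=data["explained_variance"],
                explained_variance_ratio=data["explained_variance_ratio"],
            )


def reduce_pca(
    features: np.ndarray,
    target_dim: int | None = None,
) -> tuple[np.ndarray, PCAReducer]:
    """Project features onto their top ``target_dim`` principal components.

    ``target_dim`` defaults to D // 2 (halving the representation).  If
    the data rank is below the target, only the rank components are kept,
    with a warning.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be an (N, D) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    n, d = x.shape
    if target_dim is None:
        target_dim = d // 2
    if target_dim < 1:
        raise ValueError("target_dim must be >= 1")
    if n <= target_dim:
        raise ValueError(f"need more than target_dim={target_dim} samples, got {n}")
    pca = PCA(n_components=min(target_dim, d), svd_solver="full")
    reduced = pca.fit_transform(x)
    # effective rank: components with non-negligible singular value
    sv = pca.singular_values_
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size and sv[0] > 0 else 0
    if rank < target_dim:
        warnings.warn(
            f"feature matrix rank {rank} < target_dim {target_dim}; "
            f"keeping {rank} components",
            stacklevel=2,
        )
        reduced = reduced[:, :rank]
        reducer = PCAReducer(
            mean=pca.mean_,
            components=pca.components_[:rank],
            explained_variance=pca.explained_variance_[:rank],
            explained_variance_ratio=pca.explained_variance_ratio_[:rank],
        )
    else:
        reducer = PCAReducer(
            mean=pca.mean_,
            components=pca.components_,
            explained_variance=pca.explained_variance_,
            explained_variance_ratio=pca.explained_variance_ratio_,
        )
    return reduced, reducer


# --------------------------------------------------------------------------
# Gaussian mixture via EM
# --------------------------------------------------------------------------


@dataclass
class MixtureModel:
    """A fitted K-component Gaussian mixture with its EM trace."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    seed: int = 0
    ridge: float = 1e-6

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def log_prob_components(self, x: np.ndarray) -> np.ndarray:
        """log [pi_k N(x | mu_k, Sigma_k)] for every point and component."""
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.dim:
            raise ValueError(f"dimension mismatch: model d={self.dim}, data d={x.shape[1]}")
        return _weighted_log_densities(x, self.weights, self.means, self.covariances)

    def log_likelihood(self, x: np.ndarray) -> float:
        return float(logsumexp(self.log_prob_components(x), axis=1).sum())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "log_likelihood_trace": self.log_likelihood_trace,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "ridge": self.ridge,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MixtureModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            weights=np.array(payload["weights"]),
            means=np.array(payload["means"]),
            covariances=np.array(payload["covariances"]),
            log_likelihood_trace=list(payload["log_likelihood_trace"]),
            converged=bool(payload["converged"]),
            n_iter=int(payload["n_iter"]),
            seed=int(payload["seed"]),
            ridge=float(payload["ridge"]),
        )


@dataclass
class ClusterAssignment:
    """Posterior cluster membership of one tumour tile."""

    slide_id: str
    grid_row: int
    grid_col: int
    cluster_id: int
    responsibilities: np.ndarray  # (K,), sums to 1

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.slide_id, self.grid_row, self.grid_col)


def _weighted_log_densities(
    x: np.ndarray, weights: np.ndarray, means: np.ndarray, covariances: np.ndarray
) -> np.ndarray:
    n, d = x.shape
    k = len(weights)
    out = np.empty((n, k))
    for j in range(k):
        try:
            chol = cholesky(covariances[j], lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"component {j}: covariance not positive definite"
            ) from exc
        diff = x - means[j]
        sol = cho_solve((chol, True), diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, j] = (
            np.log(weights[j])
            - 0.5 * (d * np.log(2 * np.pi) + logdet + maha)
        )
    return out


def _m_step(
    x: np.ndarray, resp: np.ndarray, ridge: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = x.shape
    nk = resp.sum(axis=0) + 10 * np.finfo(float).eps
    weights = nk / n
    means = (resp.T @ x) / nk[:, None]
    k = resp.shape[1]
    covs = np.empty((k, d, d))
    for j in range(k):
        diff = x - means[j]
        covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]
        covs[j].flat[:: d + 1] += ridge
    return weights, means, covs


def em_step_loop(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    covariances: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-4,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool, int]:
    """Run EM from explicit initial parameters.

    Returns (weights, means, covariances, log-likelihood trace, converged,
    n_iter).  Convergence follows the change in mean per-sample
    log-likelihood falling below ``tol``.  The trace records the total
    log-likelihood evaluated at each E-step plus a final evaluation at
    the returned parameters, so it is non-decreasing end to end.
    """
    n = len(x)
    trace: list[float] = []
    converged = False
    prev_mean_ll = -np.inf
    n_iter = 0
    for it in range(max_iter):
        wld = _weighted_log_densities(x, weights, means, covariances)
        log_norm = logsumexp(wld, axis=1)
        trace.append(float(log_norm.sum()))
        resp = np.exp(wld - log_norm[:, None])
        mean_ll = trace[-1] / n
        n_iter = it + 1
        if abs(mean_ll - prev_mean_ll) < tol:
            converged = True
            break
        prev_mean_ll = mean_ll
        weights, means, covariances = _m_step(x, resp, ridge)
    # log-likelihood at the final parameters
    final_ll = float(
        logsumexp(_weighted_log_densities(x, weights, means, covariances), axis=1).sum()
    )
    trace.append(final_ll)
    return weights, means, covariances, trace, converged, n_iter


def fit_gmm(
    reduced: np.ndarray,
    K: int,
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 200,
    tol: float = 1e-4,
    ridge: float = 1e-6,
    init_params: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    reorder_by_weight: bool = True,
) -> MixtureModel:
    """Fit a K-component full-covariance Gaussian mixture by EM.

    Initialisation is k-means (seeded); the best of ``n_init`` restarts
    by final log-likelihood is kept.  ``init_params`` bypasses the
    restarts and runs a single EM from the given
    (weights, means, covariances) — used for oracle-equivalence checks.
    A small ridge keeps covariances positive definite; singular inputs
    trigger a warning, not a failure.
    """
    x = np.asarray(reduced, dtype=float)
    if x.ndim != 2:
        raise ValueError("reduced features must be an (N, d) matrix")
    n, d = x.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise ValueError(f"need at least K={K} samples, got {n}")

    candidates: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    if init_params is not None:
        candidates.append(
            (
                np.asarray(init_params[0], dtype=float).copy(),
                np.asarray(init_params[1], dtype=float).copy(),
                np.asarray(init_params[2], dtype=float).copy(),
            )
        )
    else:
        for i in range(n_init):
            km = KMeans(n_clusters=K, n_init=1, random_state=seed + i)
            labels = km.fit_predict(x)
            resp = np.zeros((n, K))
            resp[np.arange(n), labels] = 1.0
            candidates.append(_m_step(x, resp, ridge))

    best: MixtureModel | None = None
    for w0, m0, c0 in candidates:
        if np.any(np.linalg.eigvalsh(c0) <= 0):
            warnings.warn(
                "singular initial covariance; applying ridge regularisation",
                stacklevel=2,
            )
            for j in range(K):
                c0[j].flat[:: d + 1] += ridge
        w, m, c, trace, converged, n_iter = em_step_loop(
            x, w0, m0, c0, max_iter=max_iter, tol=tol, ridge=ridge
        )
        model = MixtureModel(
            weights=w,
            means=m,
            covariances=c,
            log_likelihood_trace=trace,
            converged=converged,
            n_iter=n_iter,
            seed=seed,
            ridge=ridge,
        )
        if best is None or trace[-1] > best.log_likelihood_trace[-1]:
            best = model
    assert best is not None
    if reorder_by_weight:
        order = np.argsort(-best.weights, kind="stable")
        best.weights = best.weights[order]
        best.means = best.means[order]
        best.covariances = best.covariances[order]
    return best


def assign_clusters(
    model: MixtureModel,
    reduced: np.ndarray,
    keys: Sequence[tuple[str, int, int]] | None = None,
) -> list[ClusterAssignment]:
    """Posterior responsibilities and argmax hard labels for each tile.

    ``keys`` supplies (slide_id, grid_row, grid_col) per row; anonymous
    rows get a synthetic slide id.
    """
    x = np.asarray(reduced, dtype=float)
    wld = model.log_prob_components(x)
    log_norm = logsumexp(wld, axis=1)
    resp = np.exp(wld - log_norm[:, None])
    if keys is None:
        keys = [("_anon", 0, i) for i in range(len(x))]
    if len(keys) != len(x):
        raise ValueError("keys length does not match the feature matrix")
    return [
        ClusterAssignment(
            slide_id=k[0],
            grid_row=int(k[1]),
            grid_col=int(k[2]),
            cluster_id=int(np.argmax(r)),
            responsibilities=r,
        )
        for k, r in zip(keys, resp)
    ]


def map_clusters_to_types(
    assignments: Sequence[ClusterAssignment],
    reference_labels: dict[tuple[str, int, int], str],
    tie_break: str | None = None,
) -> tuple[dict[int, str], "np.ndarray | object"]:
    """Map each cluster to the majority tumour type among reference tiles.

    ``reference_labels`` carries per-tile tumour types from slides with an
    unambiguous diagnosis.  Returns (cluster -> type, composition table);
    the table gives per-cluster tile counts and percentage of each type.
    An exact within-cluster tie is refused unless ``tie_break`` names the
    type to prefer.  Two clusters mapping to the same type is legitimate
    (reported with a warning).
    """
    import pandas as pd

    counts: dict[int, dict[str, int]] = {}
    for a in assignments:
        label = reference_labels.get(a.key)
        if label is None:
            continue
        counts.setdefault(a.cluster_id, {}).setdefault(label, 0)
        counts[a.cluster_id][label] += 1
    if not counts:
        raise ValueError("no assignment matched a reference label")

    mapping: dict[int, str] = {}
    rows = []
    for cid in sorted(counts):
        by_type = counts[cid]
        total = sum(by_type.values())
        best = max(by_type.values())
        winners = sorted(t for t, c in by_type.items() if c == best)
        if len(winners) > 1:
            if tie_break is None or tie_break not in winners:
                raise ValueError(
                    f"cluster {cid}: majority tie between {winners}; "
                    f"pass tie_break to resolve"
                )
            winner = tie_break
        else:
            winner = winners[0]
        mapping[cid] = winner
        for t, c in sorted(by_type.items()):
            rows.append(
                {
                    "cluster_id": cid,
                    "tumour_type": t,
                    "n_tiles": c,
                    "pct_of_cluster": 100.0 * c / total,
                }
            )
    if len(set(mapping.values())) < len(mapping):
        warnings.warn(
            f"multiple clusters map to the same tumour type: {mapping}",
            stacklevel=2,
        )
    return mapping, pd.DataFrame(rows)


# default palette: cluster 0 green, cluster 1 blue, then matplotlib tab colours
_CLUSTER_COLOURS = np.array(
    [
        [44, 160, 44],
        [31, 119, 180],
        [255, 127, 14],
        [214, 39, 40],
        [148, 103, 189],
    ],
    dtype=np.uint8,
)


def reconstruct_label_map(
    slide: SlideImage,
    assignments: Sequence[ClusterAssignment],
    window: int,
    colours: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Paint each assigned tile window with its cluster colour.

    Returns an RGB raster the size of the slide; unassigned regions keep
    the original pixels (dimmed) so the tissue outline stays visible.
    """
    if colours is None:
        colours = _CLUSTER_COLOURS
    h, w = slide.shape
    if background is None:
        out = (slide.pixel_array.astype(float) * 0.35 + 255 * 0.65).astype(np.uint8)
    else:
        out = background.copy()
    for a in assignments:
        if a.slide_id != slide.slide_id:
            continue
        r0, c0 = a.grid_row * window, a.grid_col * window
        if r0 + window > h or c0 + window > w:
            raise KeyError(
                f"assignment {a.key} falls outside slide {slide.slide_id!r}"
            )
        out[r0 : r0 + window, c0 : c0 + window] = colours[a.cluster_id % len(colours)]
    return out
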