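"""PCA reduction and Gaussian-mixture EM: oracles and invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from histoclust.clustering import (
    ClusterAssignment,
    assign_clusters,
    fit_gmm,
    map_clusters_to_types,
    reconstruct_label_map,
    reduce_pca,
)
from histoclust.tiling import SlideImage

RIDGE = 1e-6


def oracle_em(x, weights, means, covs, max_iter=200, tol=1e-4):
    """Independent brute-force EM: explicit densities, no shared code paths."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    k = len(weights)
    weights, means, covs = (np.array(weights, dtype=float),
                            np.array(means, dtype=float), np.array(covs, dtype=float))
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        dens = np.zeros((n, k))
        for j in range(k):
            dens[:, j] = weights[j] * multivariate_normal.pdf(
                x, mean=means[j], cov=covs[j], allow_singular=False
            )
        total = dens.sum(axis=1)
        trace.append(float(np.log(total).sum()))
        if abs(trace[-1] / n - prev) < tol:
            break
        prev = trace[-1] / n
        resp = dens / total[:, None]
        nk = resp.sum(axis=0)
        weights = nk / n
        for j in range(k):
            means[j] = (resp[:, j] @ x) / nk[j]
            diff = x - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j] + RIDGE * np.eye(d)
    dens = np.zeros((n, k))
    for j in range(k):
        dens[:, j] = weights[j] * multivariate_normal.pdf(x, mean=means[j], cov=covs[j])
    final_ll = float(np.log(dens.sum(axis=1)).sum())
    return weights, means, covs, final_ll


class TestPCA:
    def test_planar_data_reconstructs_exactly(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 4))
        coeffs = rng.normal(size=(50, 2))
        x = coeffs @ basis + rng.normal(size=4)
        reduced, reducer = reduce_pca(x, target_dim=2)
        recon = reduced @ reducer.components + reducer.mean
        assert np.max(np.abs(recon - x)) < 1e-9

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 6)) @ rng.normal(size=(6, 6))
        reduced, reducer = reduce_pca(x, target_dim=3)
        centred = x - x.mean(axis=0)
        cov = centred.T @ centred / (len(x) - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert reducer.explained_variance == pytest.approx(eigvals[:3], rel=1e-9)
        assert reducer.explained_variance_ratio == pytest.approx(
            eigvals[:3] / eigvals.sum(), rel=1e-9
        )

    def test_default_target_halves_dimension(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 8))
        reduced, reducer = reduce_pca(x)
        assert reduced.shape == (60, 4)

    def test_transform_is_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 6))
        _, reducer = reduce_pca(x, target_dim=3)
        assert np.array_equal(reducer.transform(x), reducer.transform(x))

    def test_rank_deficient_input_keeps_rank_components(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=(30, 1))
        x = np.hstack([col, 2 * col, -col, 0.5 * col])  # rank 1
        with pytest.warns(UserWarning, match="rank"):
            reduced, reducer = reduce_pca(x, target_dim=2)
        assert reduced.shape[1] == 1

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        _, reducer = reduce_pca(rng.normal(size=(30, 6)), target_dim=3)
        with pytest.raises(ValueError, match="dimension"):
            reducer.transform(rng.normal(size=(5, 4)))


class TestFitGMM:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 3))
        model = fit_gmm(x, K=1, seed=0, n_init=1)
        assert model.weights == pytest.approx([1.0])
        assert model.means[0] == pytest.approx(x.mean(axis=0), abs=1e-9)
        ml_cov = np.cov(x.T, bias=True) + RIDGE * np.eye(3)
        assert model.covariances[0] == pytest.approx(ml_cov, abs=1e-8)

    def test_tiny_instance_matches_bruteforce_oracle(self):
        x = np.array([[-2.1], [-1.9], [-2.0], [2.0], [2.2], [1.8]])
        w0 = np.array([0.5, 0.5])
        m0 = np.array([[-1.0], [1.0]])
        c0 = np.array([[[1.0]], [[1.0]]])
        model = fit_gmm(x, K=2, init_params=(w0, m0, c0), reorder_by_weight=False,
                        tol=1e-10)
        ow, om, oc, oll = oracle_em(x, w0, m0, c0, tol=1e-10)
        assert model.log_likelihood_trace[-1] == pytest.approx(oll, abs=1e-6)
        assert model.weights == pytest.approx(ow, abs=1e-6)
        assert model.means == pytest.approx(om, abs=1e-6)
        assert model.covariances == pytest.approx(oc, abs=1e-6)

    def test_well_separated_gaussians_recovered(self):
        rng = np.random.default_rng(42)
        a = rng.normal(loc=[-5, 0], size=(500, 2))
        b = rng.normal(loc=[5, 0], size=(500, 2))
        x = np.vstack([a, b])
        truth = np.array([0] * 500 + [1] * 500)
        model = fit_gmm(x, K=2, seed=0)
        centres = model.means[np.argsort(model.means[:, 0])]
        assert np.linalg.norm(centres[0] - [-5, 0]) < 0.2
        assert np.linalg.norm(centres[1] - [5, 0]) < 0.2
        labels = np.array([a.cluster_id for a in assign_clusters(model, x)])
        acc = max((labels == truth).mean(), (labels == 1 - truth).mean())
        assert acc >= 0.99

    @given(
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        k=st.integers(min_value=1, max_value=3),
        sep=st.floats(min_value=0.0, max_value=4.0),
    )
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_em_trace_monotone(self, seed, k, sep):
        """The EM log-likelihood trace never decreases, for any K and
        separation, including the K=1 and fully overlapping regimes."""
        rng = np.random.default_rng(seed)
        x = np.vstack([rng.normal(size=(60, 2)), rng.normal(loc=sep, size=(60, 2))])
        model = fit_gmm(x, K=k, seed=seed % 1000)
        diffs = np.diff(model.log_likelihood_trace)
        assert (diffs >= -1e-7).all()

    def test_component_permutation_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(size=(50, 2)), rng.normal(loc=3.0, size=(50, 2))])
        model = fit_gmm(x, K=2, seed=0)
        ll = model.log_likelihood(x)
        model.weights = model.weights[::-1].copy()
        model.means = model.means[::-1].copy()
        model.covariances = model.covariances[::-1].copy()
        assert model.log_likelihood(x) == pytest.approx(ll, abs=1e-9)

    def test_clusters_ordered_by_descending_weight(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(size=(150, 1)), rng.normal(loc=6.0, size=(50, 1))])
        model = fit_gmm(x, K=2, seed=0)
        assert model.weights[0] >= model.weights[1]

    def test_matches_sklearn_from_identical_initialisation(self):
        """Cross-check against an independent EM implementation."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(size=(40, 2)), rng.normal(loc=3.0, size=(40, 2))])
        w0 = np.array([0.5, 0.5])
        m0 = np.array([[0.0, 0.0], [3.0, 3.0]])
        c0 = np.array([np.eye(2), np.eye(2)])
        model = fit_gmm(x, K=2, init_params=(w0, m0, c0), reorder_by_weight=False,
                        tol=1e-8, ridge=1e-6)
        gm = GaussianMixture(
            n_components=2, covariance_type="full", reg_covar=1e-6, tol=1e-8,
            max_iter=200, weights_init=w0, means_init=m0,
            precisions_init=np.linalg.inv(c0),
        ).fit(x)
        assert model.weights == pytest.approx(gm.weights_, abs=1e-5)
        assert model.means == pytest.approx(gm.means_, abs=1e-5)
        assert model.covariances == pytest.approx(gm.covariances_, abs=1e-5)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        model = fit_gmm(rng.normal(size=(30, 2)), K=2, seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        from histoclust.clustering import MixtureModel

        loaded = MixtureModel.from_json(path)
        assert loaded.weights == pytest.approx(model.weights)
        assert loaded.covariances == pytest.approx(model.covariances)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="K"):
            fit_gmm(np.zeros((5, 2)), K=0)
        with pytest.raises(ValueError, match="at least"):
            fit_gmm(np.zeros((1, 2)), K=2)


@pytest.fixture(scope="module")
def separated_model():
    rng = np.random.default_rng(11)
    x = np.vstack([rng.normal(loc=-5, size=(200, 2)), rng.normal(loc=5, size=(200, 2))])
    return fit_gmm(x, K=2, seed=0), x


class TestAssignClusters:
    def test_point_at_component_mean_dominates(self, separated_model):
        model, _ = separated_model
        out = assign_clusters(model, model.means)
        for j, a in enumerate(out):
            assert a.responsibilities[a.cluster_id] > 0.99
            assert a.cluster_id == j

    def test_responsibilities_sum_to_one(self, separated_model):
        model, x = separated_model
        out = assign_clusters(model, x)
        sums = np.array([a.responsibilities.sum() for a in out])
        assert sums == pytest.approx(1.0, abs=1e-9)

    def test_hard_labels_match_density_oracle(self, separated_model):
        model, x = separated_model
        out = assign_clusters(model, x[:50])
        for a, point in zip(out, x[:50]):
            dens = [
                model.weights[j]
                * multivariate_normal.pdf(point, model.means[j], model.covariances[j])
                for j in range(model.K)
            ]
            assert a.cluster_id == int(np.argmax(dens))

    def test_dimension_mismatch_errors(self, separated_model):
        model, _ = separated_model
        with pytest.raises(ValueError, match="dimension"):
            assign_clusters(model, np.zeros((3, 5)))


def _assignment(sid, row, col, cid, k=2):
    resp = np.zeros(k)
    resp[cid] = 1.0
    return ClusterAssignment(sid, row, col, cid, resp)


class TestClusterTypeMapping:
    def test_majority_composition_reported(self):
        assigns = [_assignment("s", 0, i, 0) for i in range(100)]
        refs = {("s", 0, i): ("HCC" if i < 76 else "iCCA") for i in range(100)}
        mapping, table = map_clusters_to_types(assigns, refs)
        assert mapping == {0: "HCC"}
        row = table[(table.cluster_id == 0) & (table.tumour_type == "HCC")]
        assert row.pct_of_cluster.iloc[0] == pytest.approx(76.0)

    def test_icca_dominant_cluster(self):
        assigns = [_assignment("s", 0, i, 1) for i in range(100)]
        refs = {("s", 0, i): ("iCCA" if i < 92 else "HCC") for i in range(100)}
        mapping, table = map_clusters_to_types(assigns, refs)
        assert mapping == {1: "iCCA"}
        row = table[(table.cluster_id == 1) & (table.tumour_type == "iCCA")]
        assert row.pct_of_cluster.iloc[0] == pytest.approx(92.0)

    def test_exact_tie_refused_without_policy(self):
        assigns = [_assignment("s", 0, i, 0) for i in range(10)]
        refs = {("s", 0, i): ("HCC" if i < 5 else "iCCA") for i in range(10)}
        with pytest.raises(ValueError, match="tie"):
            map_clusters_to_types(assigns, refs)
        mapping, _ = map_clusters_to_types(assigns, refs, tie_break="HCC")
        assert mapping == {0: "HCC"}

    def test_two_clusters_same_type_warns(self):
        assigns = [_assignment("s", 0, i, i % 2) for i in range(10)]
        refs = {("s", 0, i): "HCC" for i in range(10)}
        with pytest.warns(UserWarning, match="same tumour type"):
            mapping, _ = map_clusters_to_types(assigns, refs)
        assert mapping == {0: "HCC", 1: "HCC"}


class TestLabelMap:
    def test_uniform_cluster_paints_single_colour(self):
        slide = SlideImage("s", np.full((128, 128, 3), 255, dtype=np.uint8), 1.0)
        assigns = [_assignment("s", r, c, 0) for r in range(2) for c in range(2)]
        out = reconstruct_label_map(slide, assigns, window=64)
        colours = np.unique(out.reshape(-1, 3), axis=0)
        assert len(colours) == 1

    def test_painted_windows_match_grid(self):
        slide = SlideImage("s", np.full((128, 192, 3), 255, dtype=np.uint8), 1.0)
        assigns = [_assignment("s", 0, 0, 0), _assignment("s", 1, 2, 1)]
        out = reconstruct_label_map(slide, assigns, window=64)
        assert (out[:64, :64] == out[0, 0]).all()
        assert (out[64:, 128:] == out[64, 128]).all()
        assert not np.array_equal(out[0, 0], out[64, 128])
        # unpainted window keeps the dimmed background
        assert not np.array_equal(out[0, 70], out[0, 0])
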