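import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedipca import (
    CenterStatistics,
    FederatedPCA,
    aggregate_statistics,
    compute_local_statistics,
    fit_global_pca,
    flatten_masked_volume,
    transform,
    variance_retained,
)
from fedipca.fipca import GlobalPCAModel

from conftest import make_feature_matrix


def centralized_scatter(X):
    """Oracle: pooled mean and scatter computed directly, no batching."""
    mu = X.mean(axis=0)
    Xc = X - mu
    return mu, Xc.T @ Xc


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------

def test_flatten_identity_mask_preserves_values(rng):
    vol = rng.normal(size=(4, 4, 4))
    out = flatten_masked_volume(vol, np.ones((4, 4, 4)))
    assert out.shape == (64,)
    assert np.array_equal(out, vol.ravel(order="C"))


def test_flatten_zero_mask_annihilates(rng):
    vol = rng.normal(size=(4, 4, 4))
    assert np.all(flatten_masked_volume(vol, np.zeros((4, 4, 4))) == 0.0)


def test_flatten_counts_masked_voxels(rng):
    mask = np.zeros((4, 4, 4))
    idx = rng.choice(64, size=10, replace=False)
    mask.ravel()[idx] = 1
    out = flatten_masked_volume(np.ones((4, 4, 4)), mask)
    assert out.sum() == 10


def test_flatten_shape_mismatch_errors():
    with pytest.raises(ValueError, match="shape"):
        flatten_masked_volume(np.ones((4, 4, 4)), np.ones((4, 4, 3)))


# ---------------------------------------------------------------------------
# local statistics / aggregation — hand-worked examples
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mode", ["pooled_exact", "paper_literal"])
def test_two_point_site_statistics(mode):
    stats = compute_local_statistics(np.array([[0.0], [2.0]]), 2, mode)
    assert stats.mean_vector == pytest.approx([1.0])
    assert stats.scatter_matrix[0, 0] == pytest.approx(2.0)


def test_batched_scatter_modes_differ_on_worked_example():
    X = np.array([[0.0], [2.0], [4.0], [6.0]])
    pooled = compute_local_statistics(X, 2, "pooled_exact")
    literal = compute_local_statistics(X, 2, "paper_literal")
    assert pooled.scatter_matrix[0, 0] == pytest.approx(20.0)
    assert literal.scatter_matrix[0, 0] == pytest.approx(4.0)
    assert pooled.mean_vector == pytest.approx([3.0])
    assert literal.mean_vector == pytest.approx([3.0])


@pytest.mark.parametrize("mode", ["pooled_exact", "paper_literal"])
def test_single_row_gives_zero_scatter(mode, rng):
    row = rng.normal(size=(1, 5))
    stats = compute_local_statistics(row, 3, mode)
    assert stats.mean_vector == pytest.approx(row[0])
    assert np.allclose(stats.scatter_matrix, 0.0, atol=1e-12)


def test_aggregate_two_sites_equals_pooled_scatter():
    a = compute_local_statistics(np.array([[0.0], [2.0]]), 2, center_id="a")
    b = compute_local_statistics(np.array([[4.0], [6.0]]), 2, center_id="b")
    mu, S, n = aggregate_statistics([a, b])
    assert n == 4
    assert mu == pytest.approx([3.0])
    assert S[0, 0] == pytest.approx(20.0)


def test_aggregate_single_site_is_identity(rng):
    stats = compute_local_statistics(rng.normal(size=(9, 4)), 4)
    mu, S, n = aggregate_statistics([stats])
    assert n == stats.n_samples
    assert np.allclose(mu, stats.mean_vector)
    assert np.allclose(S, stats.scatter_matrix)


@pytest.mark.parametrize("mode", ["pooled_exact", "paper_literal"])
def test_identical_site_means_have_no_cross_term(mode, rng):
    X = rng.normal(size=(6, 3))
    shared = X - X.mean(axis=0)  # both sites get mean-zero data
    a = compute_local_statistics(shared, 6, mode, "a")
    b = compute_local_statistics(shared, 6, mode, "b")
    _, S, _ = aggregate_statistics([a, b])
    assert np.allclose(S, a.scatter_matrix + b.scatter_matrix, atol=1e-10)


def test_aggregate_rejects_mixed_dimension_or_mode(rng):
    a = compute_local_statistics(rng.normal(size=(5, 3)), 5)
    b = compute_local_statistics(rng.normal(size=(5, 4)), 5)
    with pytest.raises(ValueError, match="dimension"):
        aggregate_statistics([a, b])
    c = compute_local_statistics(rng.normal(size=(5, 3)), 5, "paper_literal")
    with pytest.raises(ValueError, match="mode"):
        aggregate_statistics([a, c])


def test_statistics_schema_carries_no_per_case_fields():
    # the privacy surface: only (id, N, mean, scatter, mode) cross sites
    names = {f.name for f in dataclasses.fields(CenterStatistics)}
    assert names == {"center_id", "n_samples", "mean_vector", "scatter_matrix",
                     "mode"}


# ---------------------------------------------------------------------------
# eigendecomposition and projection
# ---------------------------------------------------------------------------

def test_axis_aligned_covariance():
    model = fit_global_pca(np.zeros(2), np.diag([4.0, 0.0]), 1, k=1)
    assert model.eigenvalues == pytest.approx([4.0])
    assert model.components[:, 0] == pytest.approx([1.0, 0.0])
    assert variance_retained(model) == pytest.approx(1.0)


def test_complete_basis_retains_all_variance(rng):
    X = rng.normal(size=(30, 5))
    mu, S = centralized_scatter(X)
    model = fit_global_pca(mu, S, 30, k=5)
    assert variance_retained(model) == pytest.approx(1.0, abs=1e-10)
    # orthonormality
    WtW = model.components.T @ model.components
    assert np.abs(WtW - np.eye(5)).max() < 1e-8


def test_eigenvalues_match_centralized_pca_oracle(rng):
    X = rng.normal(size=(40, 6)) @ np.diag([3.0, 2.0, 1.5, 1.0, 0.5, 0.2])
    sites = [X[:13], X[13:27], X[27:]]
    stats = [compute_local_statistics(s, 5, center_id=str(i))
             for i, s in enumerate(sites)]
    mu, S, n = aggregate_statistics(stats)
    model = fit_global_pca(mu, S, n, k=4)
    mu_o, S_o = centralized_scatter(X)
    ref = np.linalg.eigvalsh(S_o / 40)[::-1][:4]
    assert np.allclose(model.eigenvalues, ref, atol=1e-8)


def test_fit_rejects_bad_inputs():
    with pytest.raises(ValueError, match="k"):
        fit_global_pca(np.zeros(2), np.eye(2), 4, k=3)
    bad = np.array([[1.0, 5.0], [0.0, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        fit_global_pca(np.zeros(2), bad, 4, k=1)


def test_transform_centers_and_projects(rng):
    X = rng.normal(size=(20, 4))
    mu, S = centralized_scatter(X)
    model = fit_global_pca(mu, S, 20, k=4)
    # a row equal to the global mean maps to zero
    assert np.allclose(transform(mu[None, :], model), 0.0, atol=1e-10)
    # k = d: projection is an isometry of the centered data
    Z = transform(X, model)
    assert np.allclose(np.linalg.norm(Z, axis=1),
                       np.linalg.norm(X - mu, axis=1), atol=1e-8)


def test_identity_components_reduce_to_centering(rng):
    X = rng.normal(size=(10, 3))
    model = GlobalPCAModel(
        global_mean=X.mean(axis=0), components=np.eye(3),
        eigenvalues=np.ones(3), n_total=10, total_variance=3.0,
    )
    assert np.allclose(transform(X, model), X - X.mean(axis=0))


def test_projected_variance_equals_eigenvalues(rng):
    X = rng.normal(size=(50, 6)) @ rng.normal(size=(6, 6))
    mu, S = centralized_scatter(X)
    model = fit_global_pca(mu, S, 50, k=2)
    Z = transform(X, model)
    assert np.allclose(Z.var(axis=0), model.eigenvalues, atol=1e-6)


def test_transform_carries_metadata_for_inference_only_site(rng):
    X = rng.normal(size=(8, 4))
    mu, S = centralized_scatter(X)
    model = fit_global_pca(mu, S, 8, k=2)
    fm = make_feature_matrix(rng.normal(size=(5, 4)), [0, 1, 0, 1, 0])
    out = transform(fm, model)
    assert np.array_equal(out.labels, fm.labels)
    assert np.array_equal(out.case_ids, fm.case_ids)
    with pytest.raises(ValueError, match="features"):
        transform(rng.normal(size=(5, 3)), model)


def test_variance_retained_examples():
    m = fit_global_pca(np.zeros(2), np.diag([3.0, 1.0]), 1, k=1)
    assert variance_retained(m) == pytest.approx(0.75)
    with pytest.raises(ValueError, match="k"):
        fit_global_pca(np.zeros(2), np.diag([3.0, 1.0]), 1, k=0)
    degenerate = GlobalPCAModel(np.zeros(1), np.ones((1, 1)), np.zeros(1), 2, 0.0)
    with pytest.raises(ValueError, match="variance"):
        variance_retained(degenerate)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.integers(2, 5), st.integers(2, 8))
def test_pooled_mode_matches_centralized_for_any_partition(seed, n_sites, d):
    rng = np.random.default_rng(seed)
    ns = rng.integers(2, 15, size=n_sites)
    X = rng.normal(size=(ns.sum(), d)) * rng.uniform(0.5, 3.0, size=d)
    offsets = np.concatenate([[0], np.cumsum(ns)])
    stats = []
    for i in range(n_sites):
        Xi = X[offsets[i]:offsets[i + 1]]
        b = int(rng.integers(1, len(Xi) + 1))  # ragged batches
        stats.append(compute_local_statistics(Xi, b, center_id=str(i)))
    mu, S, n = aggregate_statistics(stats)
    mu_o, S_o = centralized_scatter(X)
    scale = max(1.0, np.abs(S_o).max())
    assert np.abs(mu - mu_o).max() <= 1e-8 * max(1.0, np.abs(mu_o).max())
    assert np.abs(S - S_o).max() <= 1e-8 * scale


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 10_000))
def test_batch_size_invariance_in_pooled_mode(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(23, 4))
    results = [compute_local_statistics(X, b).scatter_matrix for b in (1, 7, 23)]
    for S in results[1:]:
        assert np.abs(S - results[0]).max() <= 1e-8 * max(1.0, np.abs(results[0]).max())


def test_components_match_centralized_up_to_sign(rng):
    # well-separated spectrum so eigenvectors are identifiable
    basis, _ = np.linalg.qr(rng.normal(size=(6, 6)))
    X = rng.normal(size=(60, 6)) * np.array([6.0, 4.0, 2.5, 1.5, 0.8, 0.3])
    X = X @ basis.T
    sites = [X[:20], X[20:45], X[45:]]
    stats = [compute_local_statistics(s, 7, center_id=str(i))
             for i, s in enumerate(sites)]
    mu, S, n = aggregate_statistics(stats)
    model = fit_global_pca(mu, S, n, k=3)
    mu_o, S_o = centralized_scatter(X)
    w, V = np.linalg.eigh(S_o / 60)
    V = V[:, np.argsort(w)[::-1]][:, :3]
    for j in range(3):
        dot = abs(model.components[:, j] @ V[:, j])
        assert dot == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# estimator interface and serialization
# ---------------------------------------------------------------------------

def test_federated_pca_is_sklearn_compatible(rng):
    from sklearn.base import clone
    from sklearn.decomposition import PCA

    X = rng.normal(size=(40, 6))
    est = FederatedPCA(n_components=3, batch_size=5)
    assert clone(est).get_params()["n_components"] == 3
    est.fit([X[:18], X[18:]])
    ref = PCA(n_components=3).fit(X)
    assert np.allclose(est.explained_variance_,
                       ref.explained_variance_ * (39 / 40), atol=1e-8)
    Z = est.transform(X)
    Zr = ref.transform(X)
    for j in range(3):  # sign-insensitive column comparison
        assert np.allclose(np.abs(Z[:, j]), np.abs(Zr[:, j]), atol=1e-6)


def test_model_and_statistics_hdf5_roundtrip(tmp_path, rng):
    X = rng.normal(size=(12, 4))
    stats = compute_local_statistics(X, 5, center_id="site_x")
    stats.save(tmp_path / "stats.h5")
    back = CenterStatistics.load(tmp_path / "stats.h5")
    assert back.center_id == "site_x"
    assert np.array_equal(back.scatter_matrix, stats.scatter_matrix)

    mu, S, n = aggregate_statistics([stats])
    model = fit_global_pca(mu, S, n, k=2)
    model.save(tmp_path / "model.h5")
    loaded = GlobalPCAModel.load(tmp_path / "model.h5")
    assert loaded.k == 2 and loaded.n_total == 12
    assert np.array_equal(loaded.components, model.components)
    assert np.allclose(transform(X, loaded), transform(X, model))
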