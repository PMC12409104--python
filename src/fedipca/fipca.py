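"""Federated incremental PCA via scatter-matrix aggregation.

Each site computes only its sample count, mean vector and scatter matrix
from batches of flattened masked volumes; the server aggregates these into
a global covariance and eigenbasis. No per-case data ever crosses sites —
the exchange objects carry aggregates only.

Two scatter conventions are provided. ``pooled_exact`` (default) centers
the accumulated second moment on the site mean and adds the between-site
mean-shift correction at aggregation, so the federated result equals a
centralized PCA of the pooled data for any batching. ``paper_literal``
accumulates each batch's scatter around its own batch mean with no
cross-batch or cross-site corrections; it is retained for fidelity
experiments and is batch-size dependent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CenterStatistics",
    "GlobalPCAModel",
    "FeatureMatrix",
    "flatten_masked_volume",
    "flatten_cohort",
    "compute_local_statistics",
    "aggregate_statistics",
    "fit_global_pca",
    "transform",
    "variance_retained",
    "FederatedPCA",
]

MODES = ("pooled_exact", "paper_literal")


@dataclass
class CenterStatistics:
    """One site's privacy-preserving summary: (N, mean, scatter).

    These three aggregates are the only payload a site ever sends; the
    schema deliberately has no per-case field.
    """

    center_id: str
    n_samples: int
    mean_vector: np.ndarray  # (d,)
    scatter_matrix: np.ndarray  # (d, d), symmetric
    mode: str = "pooled_exact"

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.scatter_matrix = np.asarray(self.scatter_matrix, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        d = self.mean_vector.shape[0]
        if self.scatter_matrix.shape != (d, d):
            raise ValueError(
                f"scatter shape {self.scatter_matrix.shape} does not match d={d}"
            )
        asym = np.abs(self.scatter_matrix - self.scatter_matrix.T).max(initial=0.0)
        scale = max(1.0, np.abs(self.scatter_matrix).max(initial=0.0))
        if asym > 1e-8 * scale:
            raise ValueError(f"scatter matrix not symmetric (max asymmetry {asym:g})")

    @property
    def d(self) -> int:
        return self.mean_vector.shape[0]

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mean", data=self.mean_vector)
            f.create_dataset("scatter", data=self.scatter_matrix)
            f.attrs["n_samples"] = self.n_samples
            f.attrs["center_id"] = self.center_id
            f.attrs["mode"] = self.mode

    @classmethod
    def load(cls, path: str | Path) -> "CenterStatistics":
        with h5py.File(path, "r") as f:
            return cls(
                center_id=str(f.attrs["center_id"]),
                n_samples=int(f.attrs["n_samples"]),
                mean_vector=f["mean"][:],
                scatter_matrix=f["scatter"][:],
                mode=str(f.attrs["mode"]),
            )


@dataclass
class GlobalPCAModel:
    """Global mean, orthonormal components W (d x k), eigenvalues, trace."""

    global_mean: np.ndarray  # (d,)
    components: np.ndarray  # (d, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), nonincreasing
    n_total: int
    total_variance: float
    mode: str = "pooled_exact"

    @property
    def d(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mean", data=self.global_mean)
            f.create_dataset("components", data=self.components)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.attrs["n_total"] = self.n_total
            f.attrs["k"] = self.k
            f.attrs["total_variance"] = self.total_variance
            f.attrs["mode"] = self.mode

    @classmethod
    def load(cls, path: str | Path) -> "GlobalPCAModel":
        with h5py.File(path, "r") as f:
            return cls(
                global_mean=f["mean"][:],
                components=f["components"][:],
                eigenvalues=f["eigenvalues"][:],
                n_total=int(f.attrs["n_total"]),
                total_variance=float(f.attrs["total_variance"]),
                mode=str(f.attrs["mode"]),
            )


@dataclass
class FeatureMatrix:
    """Cases-by-features matrix with aligned case ids and labels."""

    X: np.ndarray
    case_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (cases x features)")
        n = self.X.shape[0]
        if len(self.case_ids) != n or len(self.labels) != n:
            raise ValueError("case_ids/labels length must match row count")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def flatten_masked_volume(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the volume outside the mask and flatten in C order (axis 0 slowest).

    The full grid is kept (masked voxels become zeros rather than being
    cropped) so the feature dimension d is identical across sites, which the
    linear aggregability of scatter matrices requires.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask)
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    return (volume * (mask != 0)).ravel(order="C")


def flatten_cohort(cohort, split: str | None = None) -> FeatureMatrix:
    """Flatten every case of a cohort (optionally one split) into a FeatureMatrix."""
    idx = np.arange(cohort.n_cases)
    if split is not None:
        idx = np.flatnonzero(cohort.split == split)
    X = np.stack(
        [flatten_masked_volume(cohort.volumes[i], cohort.masks[i]) for i in idx]
    )
    return FeatureMatrix(X=X, case_ids=cohort.case_ids[idx], labels=cohort.labels[idx])


def _iter_batches(X: np.ndarray, batch_size: int) -> Iterable[np.ndarray]:
    for start in range(0, X.shape[0], batch_size):
        yield X[start : start + batch_size]


def compute_local_statistics(
    data: FeatureMatrix | np.ndarray,
    batch_size: int = 64,
    mode: str = "pooled_exact",
    center_id: str = "center",
) -> CenterStatistics:
    """Stream a site's (N, mean, scatter) over batches.

    The mean is exact over all rows regardless of batch size. In
    ``pooled_exact`` mode the scatter is around the site mean
    (sum xx^T - N mu mu^T, accumulated streaming); in ``paper_literal``
    mode each batch contributes its scatter around its own batch mean.
    """
    X = data.X if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("data must be a nonempty 2-D matrix")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    n, d = X.shape
    total = np.zeros(d)
    second = np.zeros((d, d))
    for batch in _iter_batches(X, batch_size):
        total += batch.sum(axis=0)
        if mode == "pooled_exact":
            second += batch.T @ batch
        else:
            centered = batch - batch.mean(axis=0)
            second += centered.T @ centered
    mean = total / n
    if mode == "pooled_exact":
        scatter = second - n * np.outer(mean, mean)
    else:
        scatter = second
    scatter = (scatter + scatter.T) / 2.0  # kill accumulation asymmetry
    return CenterStatistics(
        center_id=center_id, n_samples=n, mean_vector=mean,
        scatter_matrix=scatter, mode=mode,
    )


def aggregate_statistics(
    stats: Sequence[CenterStatistics],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Server-side aggregation of site statistics.

    Returns (global mean, global scatter, total count). The global mean is
    the sample-size-weighted mean of site means. In ``pooled_exact`` mode
    the global scatter adds the between-site term
    sum_i N_i (mu_i - mu)(mu_i - mu)^T, making it exactly the pooled scatter;
    in ``paper_literal`` mode site scatters are summed as-is.
    """
    if not stats:
        raise ValueError("need at least one CenterStatistics")
    d = stats[0].d
    mode = stats[0].mode
    for s in stats:
        if s.d != d:
            raise ValueError(f"mixed feature dimensions: {s.d} vs {d}")
        if s.mode != mode:
            raise ValueError(f"mixed modes: {s.mode} vs {mode}")
    n_total = sum(s.n_samples for s in stats)
    mu_global = sum(s.n_samples * s.mean_vector for s in stats) / n_total
    s_global = sum(s.scatter_matrix for s in stats)
    if mode == "pooled_exact":
        for s in stats:
            diff = s.mean_vector - mu_global
            s_global = s_global + s.n_samples * np.outer(diff, diff)
    return mu_global, s_global, n_total


def fit_global_pca(
    mu_global: np.ndarray,
    s_global: np.ndarray,
    n_total: int,
    k: int,
    mode: str = "pooled_exact",
) -> GlobalPCAModel:
    """Eigendecompose the normalized global scatter into the top-k basis.

    Cov = S_global / N_total; the top-k eigenpairs are sorted by descending
    eigenvalue and each column's sign is fixed so its largest-magnitude
    entry is positive.
    """
    s_global = np.asarray(s_global, dtype=float)
    d = s_global.shape[0]
    if s_global.shape != (d, d):
        raise ValueError("scatter must be square")
    asym = np.abs(s_global - s_global.T).max(initial=0.0)
    if asym > 1e-6 * max(1.0, np.abs(s_global).max(initial=0.0)):
        raise ValueError(f"scatter matrix not symmetric (max asymmetry {asym:g})")
    if not 1 <= k <= d:
        raise ValueError(f"k must satisfy 1 <= k <= d={d}, got {k}")

    cov = (s_global + s_global.T) / (2.0 * n_total)
    # top-k eigenpairs of the dense symmetric covariance
    eigvals, eigvecs = eigh(cov, subset_by_index=(d - k, d - 1))
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|entry| positive (first such index on ties)
    for j in range(k):
        col = eigvecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            eigvecs[:, j] = -col
    return GlobalPCAModel(
        global_mean=np.asarray(mu_global, dtype=float),
        components=eigvecs,
        eigenvalues=eigvals,
        n_total=int(n_total),
        total_variance=float(np.trace(cov)),
        mode=mode,
    )


def transform(data: FeatureMatrix | np.ndarray, model: GlobalPCAModel):
    """Project data onto the global basis: (X - mu_global) W.

    Works for sites that contributed no statistics (inference-only sites).
    Returns a FeatureMatrix when given one, else a plain array.
    """
    is_fm = isinstance(data, FeatureMatrix)
    X = data.X if is_fm else np.asarray(data, dtype=float)
    if X.shape[1] != model.d:
        raise ValueError(f"data has {X.shape[1]} features, model expects {model.d}")
    Z = (X - model.global_mean) @ model.components
    if is_fm:
        return FeatureMatrix(X=Z, case_ids=data.case_ids, labels=data.labels)
    return Z


def variance_retained(model: GlobalPCAModel) -> float:
    """Fraction of the total covariance trace captured by the kept components."""
    if model.total_variance <= 0:
        raise ValueError("total variance must be positive (constant data?)")
    return float(model.eigenvalues.sum() / model.total_variance)


class FederatedPCA(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer wrapping the federated PCA pipeline.

    ``fit`` accepts either a single (n, d) matrix (one site) or a list of
    per-site matrices; each site's statistics are computed independently in
    batches and aggregated, so the fit is identical to what the simulated
    federation produces.

    Parameters
    ----------
    n_components : number of principal components k to keep (default 10).
    batch_size : rows per local streaming batch.
    mode : "pooled_exact" (centralized-equivalent) or "paper_literal".

    Attributes (after fit)
    ----------------------
    mean_ : (d,) global mean.
    components_ : (k, d) orthonormal rows, scikit-learn convention.
    explained_variance_ : (k,) eigenvalues of the global covariance.
    total_variance_ : trace of the global covariance.
    variance_retained_ : sum(explained_variance_) / total_variance_.
    """

    def __init__(self, n_components: int = 10, batch_size: int = 64,
                 mode: str = "pooled_exact"):
        self.n_components = n_components
        self.batch_size = batch_size
        self.mode = mode

    def fit(self, X, y=None):
        sites = X if isinstance(X, (list, tuple)) else [X]
        stats = [
            compute_local_statistics(
                np.asarray(Xi, dtype=float), self.batch_size, self.mode,
                center_id=f"site_{i}",
            )
            for i, Xi in enumerate(sites)
        ]
        return self.fit_from_statistics(stats)

    def fit_from_statistics(self, stats: Sequence[CenterStatistics]):
        mu, S, n_total = aggregate_statistics(stats)
        model = fit_global_pca(mu, S, n_total, self.n_components, mode=self.mode)
        self.model_ = model
        self.mean_ = model.global_mean
        self.components_ = model.components.T
        self.explained_variance_ = model.eigenvalues
        self.total_variance_ = model.total_variance
        self.variance_retained_ = variance_retained(model)
        self.n_samples_seen_ = model.n_total
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        return transform(np.asarray(X, dtype=float), self.model_)
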