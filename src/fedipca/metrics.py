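"""Evaluation and heterogeneity diagnostics.

AUC (Mann-Whitney concordance), sensitivity/specificity, percentile
bootstrap CIs, the cross-site relative centroid distance used to quantify
harmonization, and the power x time energy estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "SiteDistanceReport",
    "roc_auc",
    "confusion_counts",
    "sensitivity_specificity",
    "bootstrap_auc_ci",
    "relative_centroid_distance",
    "pooled_standardize",
    "energy_estimate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class SiteDistanceReport:
    """Centroid distance between one site pair, before and after reduction."""

    site_a: str
    site_b: str
    raw_distance: float
    reduced_distance: float

    @property
    def percent_reduction(self) -> float:
        if self.raw_distance <= 0:
            raise ValueError("raw distance must be positive for a reduction")
        return 100.0 * (1.0 - self.reduced_distance / self.raw_distance)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; equals the Mann-Whitney concordance (ties = 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_counts(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize scores at the operating threshold and count outcomes."""
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """(tp/(tp+fn), tn/(tn+fp))."""
    if counts.positives == 0 or counts.negatives == 0:
        raise ValueError("need at least one positive and one negative case")
    return counts.tp / counts.positives, counts.tn / counts.negatives


def bootstrap_auc_ci(
    scores,
    labels,
    n_resamples: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Percentile CI for the AUC over case-level bootstrap resamples.

    Resampling is non-stratified; a resample that loses one class entirely is
    redrawn (up to ``max_retries`` consecutive attempts).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n = len(labels)
    aucs = np.empty(n_resamples)
    for i in range(n_resamples):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() != labels[idx].max():
                break
        else:
            raise RuntimeError("could not draw a two-class resample")
        aucs[i] = roc_auc(scores[idx], labels[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def relative_centroid_distance(features_a, features_b) -> float:
    """Inter-site centroid separation normalized by within-site variability.

    ||mu_a - mu_b|| / sqrt((vbar_a + vbar_b) / 2), where vbar is a site's
    mean per-feature population variance. The normalization makes the value
    invariant to a common rescaling of both sites.
    """
    A = np.atleast_2d(np.asarray(features_a, dtype=float))
    B = np.atleast_2d(np.asarray(features_b, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("both feature sets must be nonempty")
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ")
    va = A.var(axis=0).mean()
    vb = B.var(axis=0).mean()
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0.0:
        raise ValueError("both sites are constant; relative distance undefined")
    return float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)) / denom)


def pooled_standardize(feature_sets: list[np.ndarray]) -> list[np.ndarray]:
    """Standardize each feature using mean/sd pooled over all sites.

    Features with zero pooled variance (e.g. voxels outside every organ
    mask) are centered only. Used for the raw-feature arm of the distance
    diagnostic.
    """
    pooled = np.vstack(feature_sets)
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return [(F - mu) / sd for F in feature_sets]


def energy_estimate(power_watts: float, time_hours: float) -> float:
    """Energy (Wh) = power (W) x time (h)."""
    if power_watts < 0 or time_hours < 0:
        raise ValueError("power and time must be nonnegative")
    return power_watts * time_hours
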