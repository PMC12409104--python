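"""End-to-end experiment orchestration.

Generates (or loads) multi-site cohorts, fits the federated PCA basis on the
training sites only, runs the requested federated-learning arms, and
evaluates every arm on the held-out test site, which operates in
inference-only mode: it contributes no statistics and no gradients, and its
labels stay sealed in a vault until the final evaluation step.

Arms
----
adaptive        FIPCA features, accuracy-weighted aggregation, server early
                stopping — the full adaptive method.
fedavg_fixed    raw flattened features, sample-weighted FedAvg for exactly
                ``max_rounds`` rounds — the standard baseline.
fipca_only      FIPCA features, plain FedAvg, fixed rounds.
earlystop_only  raw features, plain FedAvg with the server stopper.
central         all training-site data pooled into a single locally trained
                model (upper-bound comparator, no federation loop).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import synthdata
from .client import ClientConfig, FederatedClient, ImbalanceAwareMLP, MLPNet, ClassifierSpec
from .fipca import (
    FeatureMatrix,
    FederatedPCA,
    compute_local_statistics,
    flatten_cohort,
)
from .metrics import (
    SiteDistanceReport,
    bootstrap_auc_ci,
    confusion_counts,
    energy_estimate,
    pooled_standardize,
    relative_centroid_distance,
    roc_auc,
    sensitivity_specificity,
)
from .server import FLConfig, RoundLog, run_federated_training
from .synthdata import SiteProfile, SyntheticCohort

__all__ = ["ExperimentConfig", "LabelVault", "run_experiment", "pc_sweep"]

ARMS = ("adaptive", "fedavg_fixed", "fipca_only", "earlystop_only", "central")
REPORT_SCHEMA_VERSION = 1


class LabelVault:
    """Seals the test site's labels until evaluation.

    Any read must go through :meth:`reveal`, which records the access; the
    pipeline asserts no access happened before the evaluation step.
    """

    def __init__(self, labels: np.ndarray):
        self._labels = np.asarray(labels).copy()
        self.access_count = 0

    def reveal(self) -> np.ndarray:
        self.access_count += 1
        return self._labels


@dataclass
class ExperimentConfig:
    profiles: list[SiteProfile] = field(default_factory=synthdata.default_profiles)
    test_site: str = "site_c"
    arms: tuple[str, ...] = ("adaptive", "fedavg_fixed")
    k: int = 10
    fipca_mode: str = "pooled_exact"
    fipca_batch_size: int = 64
    train_fraction: float = 0.8
    client: ClientConfig = field(default_factory=ClientConfig)
    fl: FLConfig = field(default_factory=FLConfig)
    power_bounds_watts: tuple[float, float] = (20.0, 30.0)
    operating_threshold: float = 0.5
    bootstrap_resamples: int = 1000
    seed: int = 12345

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("at least one arm is required")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arms: {sorted(unknown)}; valid: {ARMS}")
        ids = [p.site_id for p in self.profiles]
        if self.test_site not in ids:
            raise ValueError(f"test_site {self.test_site!r} not among sites {ids}")
        if len(ids) < 2:
            raise ValueError("need at least one training site plus the test site")


def _prepare_data(config: ExperimentConfig):
    """Generate cohorts, split training sites, flatten everything."""
    cohorts = synthdata.generate_multisite(config.profiles)
    by_site: dict[str, SyntheticCohort] = {}
    for i, c in enumerate(cohorts):
        if c.site_id == config.test_site:
            c.split[:] = "test"
        else:
            c = synthdata.split_train_val(c, config.train_fraction,
                                          seed=config.seed + 100 + i)
        by_site[c.site_id] = c

    train_sites = [s for s in by_site if s != config.test_site]
    features = {
        sid: {
            "train": flatten_cohort(by_site[sid], "train"),
            "val": flatten_cohort(by_site[sid], "validation"),
        }
        for sid in train_sites
    }
    test_fm = flatten_cohort(by_site[config.test_site])
    vault = LabelVault(test_fm.labels)
    # blind the working copy: downstream code never sees real test labels
    test_blind = FeatureMatrix(
        X=test_fm.X,
        case_ids=test_fm.case_ids,
        labels=np.zeros(test_fm.n, dtype=int),
    )
    return by_site, train_sites, features, test_blind, vault


def _fit_fipca(config: ExperimentConfig, train_sites, features) -> FederatedPCA:
    """Fit the global basis from training-site statistics only."""
    stats = []
    for sid in train_sites:
        X_site = np.vstack([features[sid]["train"].X, features[sid]["val"].X])
        stats.append(
            compute_local_statistics(
                X_site, config.fipca_batch_size, config.fipca_mode, center_id=sid
            )
        )
    pca = FederatedPCA(
        n_components=config.k, batch_size=config.fipca_batch_size,
        mode=config.fipca_mode,
    )
    return pca.fit_from_statistics(stats)


def _project(fm: FeatureMatrix, pca: FederatedPCA) -> FeatureMatrix:
    return FeatureMatrix(X=pca.transform(fm.X), case_ids=fm.case_ids,
                         labels=fm.labels)


_ARM_SETTINGS = {
    # (use_fipca, aggregation, early_stopping)
    "adaptive": (True, "accuracy_weighted", True),
    "fedavg_fixed": (False, "sample_weighted", False),
    "fipca_only": (True, "sample_weighted", False),
    "earlystop_only": (False, "sample_weighted", True),
}


def _predict_scores(params: np.ndarray, input_dim: int, X: np.ndarray,
                    seed: int) -> np.ndarray:
    net = MLPNet(ClassifierSpec(input_dim=input_dim, seed=seed))
    net.set_weights(params)
    p, _ = net.forward(X, training=False)
    return p


def _evaluate_arm(scores, vault: LabelVault, config: ExperimentConfig) -> dict:
    labels = vault.reveal()
    auc = roc_auc(scores, labels)
    lo, hi = bootstrap_auc_ci(
        scores, labels, n_resamples=config.bootstrap_resamples, seed=config.seed
    )
    counts = confusion_counts(scores, labels, config.operating_threshold)
    sens, spec = sensitivity_specificity(counts)
    return {
        "auc": auc,
        "auc_ci95": [lo, hi],
        "sensitivity": sens,
        "specificity": spec,
        "threshold": config.operating_threshold,
    }


def _site_distance_reports(train_sites, features, test_fm, test_site,
                           pca: FederatedPCA) -> list[SiteDistanceReport]:
    """Pairwise relative centroid distances, raw-standardized vs FIPCA space."""
    raw = {
        sid: np.vstack([features[sid]["train"].X, features[sid]["val"].X])
        for sid in train_sites
    }
    raw[test_site] = test_fm.X
    ids = list(raw)
    std = dict(zip(ids, pooled_standardize([raw[s] for s in ids])))
    reduced = {s: pca.transform(raw[s]) for s in ids}
    reports = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            reports.append(SiteDistanceReport(
                site_a=a, site_b=b,
                raw_distance=relative_centroid_distance(std[a], std[b]),
                reduced_distance=relative_centroid_distance(reduced[a], reduced[b]),
            ))
    return reports


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run every configured arm and return the report bundle."""
    by_site, train_sites, features, test_fm, vault = _prepare_data(config)
    pca = _fit_fipca(config, train_sites, features)

    distance_reports = _site_distance_reports(
        train_sites, features, test_fm, config.test_site, pca
    )

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            "sites": [p.site_id for p in config.profiles],
            "test_site": config.test_site,
            "arms": list(config.arms),
            "k": config.k,
            "fipca_mode": config.fipca_mode,
            "train_fraction": config.train_fraction,
            "max_rounds": config.fl.max_rounds,
            "seed": config.seed,
            "power_bounds_watts": list(config.power_bounds_watts),
        },
        "fipca": {
            "variance_retained": pca.variance_retained_,
            "n_total": int(pca.n_samples_seen_),
            "eigenvalues": pca.explained_variance_.tolist(),
        },
        "site_distances": [
            {
                "pair": [r.site_a, r.site_b],
                "raw": r.raw_distance,
                "reduced": r.reduced_distance,
                "percent_reduction": r.percent_reduction,
            }
            for r in distance_reports
        ],
        "arms": {},
    }
    if vault.access_count != 0:
        raise RuntimeError("test labels were read before evaluation")

    logs: dict[str, RoundLog] = {}
    for arm in config.arms:
        t0 = time.perf_counter()
        if arm == "central":
            arm_result, log = _run_central_arm(config, train_sites, features,
                                               test_fm, pca)
        else:
            arm_result, log = _run_federated_arm(arm, config, train_sites,
                                                 features, test_fm, pca)
        pre_eval_accesses = vault.access_count
        elapsed_h = (time.perf_counter() - t0) / 3600.0
        arm_result["evaluation"] = _evaluate_arm(arm_result.pop("scores"),
                                                 vault, config)
        arm_result["label_accesses_before_eval"] = pre_eval_accesses
        lo_w, hi_w = config.power_bounds_watts
        arm_result["elapsed_hours"] = elapsed_h
        arm_result["energy_wh"] = [
            energy_estimate(lo_w, elapsed_h), energy_estimate(hi_w, elapsed_h)
        ]
        report["arms"][arm] = arm_result
        if log is not None:
            logs[arm] = log

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        for arm, log in logs.items():
            log.write(out, stem=f"rounds_{arm}")
    return report


def _run_federated_arm(arm, config, train_sites, features, test_fm, pca):
    use_fipca, aggregation, early_stopping = _ARM_SETTINGS[arm]
    proj = (lambda fm: _project(fm, pca)) if use_fipca else (lambda fm: fm)
    clients = [
        FederatedClient(
            sid,
            proj(features[sid]["train"]),
            proj(features[sid]["val"]),
            config=replace(config.client, seed=config.client.seed),
        )
        for sid in train_sites
    ]
    fl = replace(config.fl, aggregation=aggregation, early_stopping=early_stopping)
    params, log = run_federated_training(clients, fl)
    scores = _predict_scores(
        params, clients[0].input_dim, proj(test_fm).X, config.client.seed
    )
    return {
        "rounds_used": log.rounds_used,
        "stop_reason": log.stop_reason,
        "aggregation": aggregation,
        "uses_fipca": use_fipca,
        "scores": scores,
    }, log


def _run_central_arm(config, train_sites, features, test_fm, pca):
    X_tr = np.vstack([_project(features[s]["train"], pca).X for s in train_sites])
    y_tr = np.concatenate([features[s]["train"].labels for s in train_sites])
    X_va = np.vstack([_project(features[s]["val"], pca).X for s in train_sites])
    y_va = np.concatenate([features[s]["val"].labels for s in train_sites])
    clf = ImbalanceAwareMLP(
        lambda_fn=config.client.loss.lambda_fn,
        lambda_fp=config.client.loss.lambda_fp,
        lambda_auc=config.client.loss.lambda_auc,
        lr=config.client.lr.lr0,
        batch_size=config.client.batch_size,
        max_epochs=200,
        patience=config.client.patience,
        seed=config.client.seed,
    )
    clf.fit(X_tr, y_tr.astype(int), X_val=X_va, y_val=y_va.astype(int))
    scores = clf.predict_proba(_project(test_fm, pca).X)[:, 1]
    return {
        "rounds_used": 0,
        "stop_reason": "central",
        "aggregation": "none",
        "uses_fipca": True,
        "epochs_run": clf.epochs_run_,
        "scores": scores,
    }, None


def pc_sweep(config: ExperimentConfig, k_values: Sequence[int]) -> list[dict]:
    """Adaptive-arm runs across component counts, sharing seeds and data.

    Returns one row per k with the stop round, test AUC and variance
    retained — the component-count-versus-rounds diagnostic.
    """
    if not k_values:
        raise ValueError("k_values must be nonempty")
    by_site, train_sites, features, test_fm, vault = _prepare_data(config)
    d = test_fm.d
    rows = []
    for k in k_values:
        if not 1 <= k <= d:
            raise ValueError(f"k={k} outside [1, {d}]")
        cfg_k = replace(config, k=k, arms=("adaptive",))
        pca = _fit_fipca(cfg_k, train_sites, features)
        arm_result, log = _run_federated_arm("adaptive", cfg_k, train_sites,
                                             features, test_fm, pca)
        auc = roc_auc(arm_result["scores"], vault.reveal())
        rows.append({
            "k": int(k),
            "stop_round": arm_result["rounds_used"],
            "stop_reason": arm_result["stop_reason"],
            "auc": auc,
            "variance_retained": pca.variance_retained_,
            "seed": config.seed,
        })
    return rows
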