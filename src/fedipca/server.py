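"""Server-side federation control.

Implements accuracy-weighted parameter aggregation

    w(t) = sum_k n_k a_k w_k / sum_k n_k a_k,

the validation-size-weighted aggregated loss

    L_t = sum_k n_val,k L_k / sum_k n_val,k,

and an adaptive early-stopping controller: an improvement of more than
``delta`` updates the best loss and resets the wait counter; a loss within
``tolerance`` of the best also resets the counter (without updating the
best); anything else increments it. Training stops once the counter reaches
``patience`` at or after ``t_min`` rounds. Setting the aggregation mode to
``sample_weighted`` and disabling the stopper reduces the loop to standard
FedAvg run for a fixed number of rounds.

The federation is simulated in-process with sequential clients; the
broadcast -> local train -> collect -> aggregate contract matches a
networked deployment, and the exchange objects are exactly what would go on
the wire.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .client import ClientUpdate, FederatedClient

__all__ = [
    "EarlyStopState",
    "FLConfig",
    "RoundLog",
    "aggregate_weights",
    "aggregate_validation_loss",
    "early_stop_step",
    "select_clients",
    "run_federated_training",
]

logger = logging.getLogger(__name__)


@dataclass
class EarlyStopState:
    """Adaptive stopping state: best loss, wait counter and its thresholds."""

    patience: int = 10
    tolerance: float = 1e-3  # epsilon: near-best band that resets the counter
    delta: float = 1e-4  # minimum decrease counted as an improvement
    t_min: int = 20
    best_loss: float = math.inf
    wait: int = 0

    def snapshot(self) -> dict:
        return asdict(self)


@dataclass
class FLConfig:
    """Federation loop settings."""

    max_rounds: int = 200
    clients_per_round: int | None = None  # None = all clients
    aggregation: str = "accuracy_weighted"  # or "sample_weighted"
    early_stopping: bool = True
    patience: int = 10
    tolerance: float = 1e-3
    delta: float = 1e-4
    t_min: int = 20
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.aggregation not in ("accuracy_weighted", "sample_weighted"):
            raise ValueError(f"unknown aggregation mode {self.aggregation!r}")


@dataclass
class RoundLog:
    """Per-round provenance of one federated run."""

    records: list[dict] = field(default_factory=list)
    stop_round: int | None = None
    stop_reason: str = "max_rounds"
    config: dict = field(default_factory=dict)

    @property
    def rounds_used(self) -> int:
        return len(self.records)

    def append(self, record: dict) -> None:
        if self.records and record["round"] <= self.records[-1]["round"]:
            raise ValueError("round numbers must be strictly increasing")
        self.records.append(record)

    def write(self, out_dir: str | Path, stem: str = "rounds") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{stem}.jsonl", "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")
        summary = {
            "stop_round": self.stop_round,
            "stop_reason": self.stop_reason,
            "rounds_used": self.rounds_used,
            "final_loss": self.records[-1]["aggregated_loss"] if self.records else None,
            "config": self.config,
        }
        with open(out / f"{stem}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def aggregate_weights(
    updates: Sequence[ClientUpdate], mode: str = "accuracy_weighted"
) -> np.ndarray:
    """Convex combination of client parameter vectors.

    ``accuracy_weighted`` uses n_k * a_k; ``sample_weighted`` (plain FedAvg)
    uses n_k. If every accuracy is zero the aggregation falls back to sample
    weighting with a logged warning rather than dividing by zero.
    """
    if not updates:
        raise ValueError("need at least one client update")
    shape = updates[0].parameters.shape
    for u in updates:
        if u.parameters.shape != shape:
            raise ValueError("client parameter shapes differ")
    if mode == "accuracy_weighted":
        w = np.array([u.n_train * u.val_accuracy for u in updates], dtype=float)
        if w.sum() == 0.0:
            logger.warning(
                "all client accuracies are zero; falling back to sample weighting"
            )
            w = np.array([u.n_train for u in updates], dtype=float)
    elif mode == "sample_weighted":
        w = np.array([u.n_train for u in updates], dtype=float)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    w = w / w.sum()
    return sum(wk * u.parameters for wk, u in zip(w, updates))


def aggregate_validation_loss(updates: Sequence[ClientUpdate]) -> float:
    """Validation-size-weighted mean of client validation losses."""
    if not updates:
        raise ValueError("need at least one client update")
    n = np.array([u.n_val for u in updates], dtype=float)
    L = np.array([u.val_loss for u in updates], dtype=float)
    return float(np.sum(n * L) / np.sum(n))


def early_stop_step(
    state: EarlyStopState, loss: float, t: int
) -> tuple[EarlyStopState, str]:
    """One controller step; returns the updated state and 'continue' or 'stop'."""
    if not math.isfinite(loss):
        raise ValueError(f"aggregated loss must be finite, got {loss}")
    if loss < state.best_loss - state.delta:
        state.best_loss = loss
        state.wait = 0
    elif loss <= state.best_loss + state.tolerance:
        state.wait = 0
    else:
        state.wait += 1
    decision = "stop" if (t >= state.t_min and state.wait >= state.patience) else "continue"
    return state, decision


def select_clients(
    client_ids: Sequence[str],
    clients_per_round: int | None,
    round_t: int,
    seed: int,
) -> list[str]:
    """Deterministic per-(seed, round) subset; default is full participation."""
    ids = list(client_ids)
    if clients_per_round is None or clients_per_round >= len(ids):
        return ids
    if clients_per_round < 1:
        raise ValueError("clients_per_round must be >= 1")
    rng = np.random.default_rng((seed, round_t))
    chosen = rng.choice(len(ids), size=clients_per_round, replace=False)
    return [ids[i] for i in sorted(chosen)]


def run_federated_training(
    clients: Sequence[FederatedClient],
    config: FLConfig,
) -> tuple[np.ndarray, RoundLog]:
    """Run the federation loop; returns (final global parameters, round log)."""
    if not clients:
        raise ValueError("need at least one client")
    dims = {c.input_dim for c in clients}
    if len(dims) != 1:
        raise ValueError(f"clients disagree on feature dimension: {sorted(dims)}")

    log = RoundLog(config={
        "max_rounds": config.max_rounds,
        "clients_per_round": config.clients_per_round,
        "aggregation": config.aggregation,
        "early_stopping": config.early_stopping,
        "patience": config.patience,
        "tolerance": config.tolerance,
        "delta": config.delta,
        "t_min": config.t_min,
        "seed": config.seed,
    })
    stopper = EarlyStopState(
        patience=config.patience, tolerance=config.tolerance,
        delta=config.delta, t_min=config.t_min,
    )
    by_id = {c.client_id: c for c in clients}
    global_w = clients[0].initial_weights()

    for t in range(1, config.max_rounds + 1):
        chosen = select_clients(
            list(by_id), config.clients_per_round, t, config.seed
        )
        updates: list[ClientUpdate] = []
        for cid in chosen:
            try:
                updates.append(by_id[cid].run_round(global_w, t))
            except Exception:
                logger.exception("client %s failed in round %d; aborting round", cid, t)
                raise
        global_w = aggregate_weights(updates, config.aggregation)
        loss_t = aggregate_validation_loss(updates)
        if config.early_stopping:
            stopper, decision = early_stop_step(stopper, loss_t, t)
        else:
            decision = "continue"
        log.append({
            "round": t,
            "clients": chosen,
            "client_metrics": [
                {
                    "n_train": u.n_train, "n_val": u.n_val,
                    "val_loss": u.val_loss, "val_accuracy": u.val_accuracy,
                    "epochs_run": u.epochs_run,
                }
                for u in updates
            ],
            "aggregated_loss": loss_t,
            "early_stop": stopper.snapshot() if config.early_stopping else None,
            "stopped": decision == "stop",
        })
        if decision == "stop":
            log.stop_round = t
            log.stop_reason = "early_stopping"
            break
    else:
        log.stop_round = config.max_rounds
        log.stop_reason = "max_rounds"
    return global_w, log
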