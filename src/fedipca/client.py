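"""Client-side training: imbalance-aware loss, LR schedule, and local fits.

The classifier is a small fully connected network — Dense(128)+BN+ReLU,
Dense(64)+BN+ReLU, Dropout(0.5), Dense(2)+softmax — trained with Adam on a
custom loss that augments cross-entropy with explicit false-negative and
false-positive penalties and a squared-error (Brier) regularizer:

    L = L_CE + lambda_fn * y (1 - p) + lambda_fp * (1 - y) p
             + lambda_auc * (p - y)^2

where p is the positive-class softmax probability. Balanced inverse-frequency
class weights multiply the per-sample loss. The learning rate decays with the
server round number in steps (by default every 25 rounds), and each local fit
early-stops on validation loss with a patience of five epochs.

The network is implemented directly on numpy (forward, backprop through batch
norm and dropout, Adam); parameters travel as a single flat vector so the
server can average them, and batch-norm running statistics are part of that
vector — they must be, for the averaged global model to be usable at
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fipca import FeatureMatrix

__all__ = [
    "LossWeights",
    "LRSchedule",
    "ClassifierSpec",
    "ClientUpdate",
    "ClientConfig",
    "MLPNet",
    "custom_loss",
    "learning_rate",
    "build_classifier",
    "class_weights",
    "local_train",
    "warm_start",
    "FederatedClient",
    "ImbalanceAwareMLP",
]

_P_EPS = 1e-7
_BN_EPS = 1e-3  # keras BatchNormalization default
_BN_MOMENTUM = 0.99


@dataclass(frozen=True)
class LossWeights:
    """Penalty coefficients (lambda_fn, lambda_fp, lambda_auc); defaults (2, 1, 0.1)."""

    lambda_fn: float = 2.0
    lambda_fp: float = 1.0
    lambda_auc: float = 0.1

    def __post_init__(self) -> None:
        for name in ("lambda_fn", "lambda_fp", "lambda_auc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LRSchedule:
    """Round-indexed exponential decay, staircase by default (steps of 25 rounds)."""

    lr0: float = 1e-3
    decay_rate: float = 0.9
    decay_steps: int = 25
    staircase: bool = True

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not 0 < self.decay_rate <= 1:
            raise ValueError("decay_rate must be in (0, 1]")
        if self.decay_steps < 1:
            raise ValueError("decay_steps must be >= 1")


@dataclass(frozen=True)
class ClassifierSpec:
    input_dim: int
    hidden: tuple[int, int] = (128, 64)
    dropout: float = 0.5
    seed: int = 12345


@dataclass
class ClientUpdate:
    """What one client returns per round: weights, sizes, validation metrics."""

    parameters: np.ndarray
    n_train: int
    n_val: int
    val_loss: float
    val_accuracy: float
    epochs_run: int

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_val < 1:
            raise ValueError("n_train and n_val must be >= 1")
        if not np.isfinite(self.parameters).all():
            raise ValueError("parameters contain non-finite values")
        if not (np.isfinite(self.val_loss) and 0 <= self.val_accuracy <= 1):
            raise ValueError("invalid validation metrics")


@dataclass
class ClientConfig:
    loss: LossWeights = field(default_factory=LossWeights)
    lr: LRSchedule = field(default_factory=LRSchedule)
    patience: int = 5
    max_epochs: int = 50
    batch_size: int = 32
    warm_start: bool = True
    warm_start_contributes: bool = True
    seed: int = 12345


def custom_loss(
    y_true,
    p,
    weights: LossWeights = LossWeights(),
    sample_weight=None,
) -> float:
    """Mean imbalance-aware loss over a batch.

    ``p`` is the predicted positive-class probability; it is clipped to
    [1e-7, 1 - 1e-7] before the logs. With all lambdas zero this is exactly
    (weighted) binary cross-entropy.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(p, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y_true must be binary (0/1)")
    pc = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    ce = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    per_sample = (
        ce
        + weights.lambda_fn * y * (1.0 - p)
        + weights.lambda_fp * (1.0 - y) * p
        + weights.lambda_auc * (p - y) ** 2
    )
    if sample_weight is not None:
        per_sample = per_sample * np.asarray(sample_weight, dtype=float)
    return float(np.mean(per_sample))


def _custom_loss_grad_p(y, p, weights: LossWeights):
    """d(per-sample loss)/dp, evaluated with the same clipping as the value."""
    pc = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    dce = -(y / pc) + (1.0 - y) / (1.0 - pc)
    return (
        dce
        - weights.lambda_fn * y
        + weights.lambda_fp * (1.0 - y)
        + 2.0 * weights.lambda_auc * (p - y)
    )


def learning_rate(t: int, schedule: LRSchedule) -> float:
    """lr0 * decay_rate**(t / decay_steps); staircase floors the exponent."""
    if t < 0:
        raise ValueError("round number t must be >= 0")
    expo = t // schedule.decay_steps if schedule.staircase else t / schedule.decay_steps
    return schedule.lr0 * schedule.decay_rate**expo


def class_weights(labels) -> tuple[float, float]:
    """Balanced inverse-frequency weights: w_c = n_total / (2 * n_c)."""
    y = np.asarray(labels)
    n_neg = int(np.sum(y == 0))
    n_pos = int(np.sum(y == 1))
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both classes must be present to compute class weights")
    n = n_neg + n_pos
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


class MLPNet:
    """The client network on plain numpy, with manual backprop and Adam.

    Parameter layout (all exchanged with the server, packed as one flat
    vector): W1, b1, gamma1, beta1, W2, b2, gamma2, beta2, W3, b3, then the
    batch-norm running means/variances. Only the first group is trainable.
    """

    TRAINABLE = ("W1", "b1", "gamma1", "beta1", "W2", "b2", "gamma2", "beta2",
                 "W3", "b3")
    RUNNING = ("rm1", "rv1", "rm2", "rv2")

    def __init__(self, spec: ClassifierSpec):
        if spec.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.spec = spec
        k, (h1, h2) = spec.input_dim, spec.hidden
        rng = np.random.default_rng(spec.seed)

        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        self.params = {
            "W1": glorot(k, h1), "b1": np.zeros(h1),
            "gamma1": np.ones(h1), "beta1": np.zeros(h1),
            "W2": glorot(h1, h2), "b2": np.zeros(h2),
            "gamma2": np.ones(h2), "beta2": np.zeros(h2),
            "W3": glorot(h2, 2), "b3": np.zeros(2),
            "rm1": np.zeros(h1), "rv1": np.ones(h1),
            "rm2": np.zeros(h2), "rv2": np.ones(h2),
        }

    # -- parameter vector interface -----------------------------------------
    @property
    def n_trainable_params(self) -> int:
        return int(sum(self.params[n].size for n in self.TRAINABLE))

    def layer_shapes(self) -> dict[str, tuple[int, ...]]:
        return {n: self.params[n].shape for n in self.TRAINABLE + self.RUNNING}

    def get_weights(self) -> np.ndarray:
        return np.concatenate(
            [self.params[n].ravel() for n in self.TRAINABLE + self.RUNNING]
        )

    def set_weights(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=float)
        expected = sum(self.params[n].size for n in self.TRAINABLE + self.RUNNING)
        if flat.size != expected:
            raise ValueError(f"expected {expected} parameters, got {flat.size}")
        pos = 0
        for n in self.TRAINABLE + self.RUNNING:
            size = self.params[n].size
            self.params[n] = flat[pos : pos + size].reshape(self.params[n].shape)
            pos += size

    # -- forward / backward --------------------------------------------------
    def _bn_forward(self, z, layer, training):
        g, b = self.params[f"gamma{layer}"], self.params[f"beta{layer}"]
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            self.params[f"rm{layer}"] = (
                _BN_MOMENTUM * self.params[f"rm{layer}"] + (1 - _BN_MOMENTUM) * mu
            )
            self.params[f"rv{layer}"] = (
                _BN_MOMENTUM * self.params[f"rv{layer}"] + (1 - _BN_MOMENTUM) * var
            )
        else:
            mu, var = self.params[f"rm{layer}"], self.params[f"rv{layer}"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        zhat = (z - mu) * inv_std
        return g * zhat + b, (z, zhat, mu, inv_std)

    def forward(self, X, training=False, dropout_rng=None):
        """Return positive-class probabilities and a cache for backprop."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input must be (n, {self.spec.input_dim}), got {X.shape}"
            )
        p = self.params
        z1 = X @ p["W1"] + p["b1"]
        h1, bn1 = self._bn_forward(z1, 1, training)
        a1 = np.maximum(h1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        h2, bn2 = self._bn_forward(z2, 2, training)
        a2 = np.maximum(h2, 0.0)
        if training and self.spec.dropout > 0:
            keep = 1.0 - self.spec.dropout
            mask = (dropout_rng.random(a2.shape) < keep) / keep
            a2d = a2 * mask
        else:
            mask = None
            a2d = a2
        logits = a2d @ p["W3"] + p["b3"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        probs = expz / expz.sum(axis=1, keepdims=True)
        cache = (X, bn1, h1, a1, bn2, h2, a2, mask, a2d, probs)
        return probs[:, 1], cache

    @staticmethod
    def _bn_backward(dh, bn, gamma):
        z, zhat, mu, inv_std = bn
        m = z.shape[0]
        dgamma = (dh * zhat).sum(axis=0)
        dbeta = dh.sum(axis=0)
        dzhat = dh * gamma
        dvar = (dzhat * (z - mu)).sum(axis=0) * (-0.5) * inv_std**3
        dmu = -(dzhat.sum(axis=0)) * inv_std + dvar * (-2.0 / m) * (z - mu).sum(axis=0)
        dz = dzhat * inv_std + dvar * 2.0 * (z - mu) / m + dmu / m
        return dz, dgamma, dbeta

    def backward(self, cache, y, loss_weights, sample_weight):
        """Gradients of the mean weighted custom loss w.r.t. trainable params."""
        X, bn1, h1, a1, bn2, h2, a2, mask, a2d, probs = cache
        p = self.params
        n = X.shape[0]
        p1 = probs[:, 1]
        dLdp = _custom_loss_grad_p(y, p1, loss_weights)
        if sample_weight is not None:
            dLdp = dLdp * sample_weight
        dLdp = dLdp / n
        # two-class softmax: dp1/dlogit1 = p1(1-p1), dp1/dlogit0 = -p1(1-p1)
        dlog1 = dLdp * p1 * (1.0 - p1)
        dlogits = np.stack([-dlog1, dlog1], axis=1)

        grads = {}
        grads["W3"] = a2d.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        da2 = dlogits @ p["W3"].T
        if mask is not None:
            da2 = da2 * mask
        dh2 = da2 * (h2 > 0)
        dz2, grads["gamma2"], grads["beta2"] = self._bn_backward(
            dh2, bn2, p["gamma2"]
        )
        grads["W2"] = a1.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        da1 = dz2 @ p["W2"].T
        dh1 = da1 * (h1 > 0)
        dz1, grads["gamma1"], grads["beta1"] = self._bn_backward(
            dh1, bn1, p["gamma1"]
        )
        grads["W1"] = X.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads


class _Adam:
    def __init__(self, names, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros(shapes[n]) for n in names}
        self.v = {n: np.zeros(shapes[n]) for n in names}

    def step(self, params, grads):
        self.t += 1
        for n, g in grads.items():
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g**2
            mhat = self.m[n] / (1 - self.b1**self.t)
            vhat = self.v[n] / (1 - self.b2**self.t)
            params[n] = params[n] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_classifier(spec: ClassifierSpec) -> MLPNet:
    """Construct the client network; initialization is deterministic per seed."""
    return MLPNet(spec)


def _evaluate(net, X, y, loss_weights, cw) -> tuple[float, float]:
    p, _ = net.forward(X, training=False)
    sw = np.where(y == 1, cw[1], cw[0]) if cw is not None else None
    loss = custom_loss(y, p, loss_weights, sample_weight=sw)
    acc = float(np.mean((p >= 0.5).astype(int) == y))
    return loss, acc


def _train_loop(
    net: MLPNet,
    X_train, y_train, X_val, y_val,
    lr: float,
    loss_weights: LossWeights,
    batch_size: int,
    max_epochs: int,
    patience: int,
    rng: np.random.Generator,
    restore_best: bool = True,
) -> tuple[float, float, int]:
    """Mini-batch Adam with early stopping on validation loss.

    Returns (val_loss, val_accuracy, epochs_run) of the restored best state.
    """
    cw = class_weights(y_train)
    sw_all = np.where(y_train == 1, cw[1], cw[0])
    opt = _Adam(MLPNet.TRAINABLE, {n: net.params[n].shape for n in MLPNet.TRAINABLE}, lr)

    best_loss, best_acc = _evaluate(net, X_val, y_val, loss_weights, cw)
    best_state = net.get_weights()
    wait = 0
    epochs_run = 0
    n = X_train.shape[0]
    for _ in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            p, cache = net.forward(X_train[idx], training=True, dropout_rng=rng)
            grads = net.backward(cache, y_train[idx], loss_weights, sw_all[idx])
            opt.step(net.params, grads)
        epochs_run += 1
        val_loss, val_acc = _evaluate(net, X_val, y_val, loss_weights, cw)
        if not np.isfinite(val_loss):
            raise RuntimeError(
                f"non-finite validation loss at epoch {epochs_run} (lr={lr})"
            )
        if val_loss < best_loss:
            best_loss, best_acc = val_loss, val_acc
            best_state = net.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    if restore_best:
        net.set_weights(best_state)
    return best_loss, best_acc, epochs_run


def local_train(
    global_params: np.ndarray | None,
    round_t: int,
    train: FeatureMatrix,
    val: FeatureMatrix,
    config: ClientConfig,
    net: MLPNet | None = None,
    rng: np.random.Generator | None = None,
) -> ClientUpdate:
    """One round of local training starting from the broadcast global weights."""
    if val.n == 0:
        raise ValueError("validation set must be nonempty")
    if net is None:
        net = build_classifier(ClassifierSpec(input_dim=train.d, seed=config.seed))
    if global_params is not None:
        net.set_weights(global_params)
    if rng is None:
        rng = np.random.default_rng(config.seed + round_t)
    lr = learning_rate(round_t, config.lr)
    y_tr = train.labels.astype(int)
    y_va = val.labels.astype(int)
    val_loss, val_acc, epochs = _train_loop(
        net, train.X, y_tr, val.X, y_va,
        lr=lr, loss_weights=config.loss,
        batch_size=config.batch_size, max_epochs=config.max_epochs,
        patience=config.patience, rng=rng,
    )
    return ClientUpdate(
        parameters=net.get_weights(),
        n_train=train.n, n_val=val.n,
        val_loss=val_loss, val_accuracy=val_acc,
        epochs_run=epochs,
    )


def warm_start(
    train: FeatureMatrix,
    val: FeatureMatrix,
    config: ClientConfig,
    net: MLPNet | None = None,
    rng: np.random.Generator | None = None,
) -> MLPNet:
    """Pre-federation local pass with plain cross-entropy (all lambdas zero)."""
    if net is None:
        net = build_classifier(ClassifierSpec(input_dim=train.d, seed=config.seed))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _train_loop(
        net, train.X, train.labels.astype(int), val.X, val.labels.astype(int),
        lr=config.lr.lr0, loss_weights=LossWeights(0.0, 0.0, 0.0),
        batch_size=config.batch_size, max_epochs=config.max_epochs,
        patience=config.patience, rng=rng,
    )
    return net


class FederatedClient:
    """One simulated site: holds its own data, trains on broadcast weights.

    If ``config.warm_start`` is on, the client runs a plain cross-entropy
    local pass at construction; with ``warm_start_contributes`` the first
    federated round then starts from those locally trained weights rather
    than the server broadcast.
    """

    def __init__(self, client_id: str, train: FeatureMatrix, val: FeatureMatrix,
                 config: ClientConfig | None = None):
        self.client_id = client_id
        self.train_data = train
        self.val_data = val
        self.config = config or ClientConfig()
        self.net = build_classifier(
            ClassifierSpec(input_dim=train.d, seed=self.config.seed)
        )
        self._rng = np.random.default_rng(self.config.seed)
        self._warm = False
        if self.config.warm_start:
            warm_start(train, val, self.config, net=self.net, rng=self._rng)
            self._warm = True

    @property
    def input_dim(self) -> int:
        return self.train_data.d

    def initial_weights(self) -> np.ndarray:
        return self.net.get_weights()

    def run_round(self, global_params: np.ndarray, round_t: int) -> ClientUpdate:
        use_warm = (
            round_t == 1 and self._warm and self.config.warm_start_contributes
        )
        start = None if use_warm else global_params
        return local_train(
            start, round_t, self.train_data, self.val_data, self.config,
            net=self.net, rng=self._rng,
        )


class ImbalanceAwareMLP:
    """Scikit-learn style classifier around :class:`MLPNet`.

    Trains with the imbalance-aware custom loss, balanced class weights and
    validation early stopping (an internal stratified split when no explicit
    validation set is passed to ``fit``).
    """

    def __init__(self, lambda_fn=2.0, lambda_fp=1.0, lambda_auc=0.1,
                 lr=1e-3, batch_size=32, max_epochs=50, patience=5,
                 val_fraction=0.2, seed=12345):
        self.lambda_fn = lambda_fn
        self.lambda_fp = lambda_fp
        self.lambda_auc = lambda_auc
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in ("lambda_fn", "lambda_fp", "lambda_auc", "lr", "batch_size",
                      "max_epochs", "patience", "val_fraction", "seed")
        }

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X_val is None:
            from sklearn.model_selection import train_test_split

            X, X_val, y, y_val = train_test_split(
                X, y, test_size=self.val_fraction, stratify=y,
                random_state=self.seed % (2**32),
            )
        self.net_ = build_classifier(ClassifierSpec(input_dim=X.shape[1],
                                                    seed=self.seed))
        rng = np.random.default_rng(self.seed)
        lw = LossWeights(self.lambda_fn, self.lambda_fp, self.lambda_auc)
        loss, acc, epochs = _train_loop(
            self.net_, X, y, np.asarray(X_val, dtype=float),
            np.asarray(y_val, dtype=int),
            lr=self.lr, loss_weights=lw, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience, rng=rng,
        )
        self.val_loss_ = loss
        self.val_accuracy_ = acc
        self.epochs_run_ = epochs
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p1, _ = self.net_.forward(np.asarray(X, dtype=float), training=False)
        return np.stack([1.0 - p1, p1], axis=1)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=int)))
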