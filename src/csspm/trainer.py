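"""Consistency-regularized semisupervised training (the CSSPM algorithm).

Each training sample — labeled or not — receives Gaussian input augmentation
and a stochastic (dropout-active) forward pass once per epoch.  An exponential
moving average of each sample's past predictions, corrected for startup bias,

    Z_i   <- alpha * Z_i + (1 - alpha) * z_i        (after every epoch)
    Z~_i  =  Z_i / (1 - alpha^t)                    (t = completed epochs)

serves as that sample's consistency target.  The loss is

    L = L_c + omega(t) * L_con

with L_c the cross-entropy over the labeled members of the minibatch, L_con
the mean squared error between current predictions and their targets over the
whole minibatch, and omega(t) a Gaussian ramp-up reaching omega_max at epoch
tau.  Optimization is Adam with a time-reversed Gaussian learning-rate
ramp-down; the checkpoint with the best validation accuracy (earliest epoch on
ties) is returned.

Setting ``omega_max = 0`` and removing unlabeled samples reproduces the plain
supervised baseline trajectory bit-for-bit under the same seed: all random
streams (shuffling, noise, dropout, initialization) are derived from
``(seed, epoch, batch)`` keys so the two code paths consume identical
randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ModelConfig, build_model
from .nn import Adam, Sequential

__all__ = [
    "TrainConfig",
    "EnsembleState",
    "FitResult",
    "CsspmClassifier",
    "augment",
    "ramp_up_weight",
    "update_ensemble",
    "supervised_loss",
    "consistency_loss",
    "total_loss",
    "lr_schedule",
    "fit",
    "fit_supervised",
]

_EPS = 1e-7  # probability clip before logs


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the reference settings).

    noise_sigma : std of the additive Gaussian augmentation, in units of the
        per-subject median absolute spectrogram amplitude.
    lr_max : maximum Adam learning rate; ramped down over the final
        ``rampdown_length`` epochs by exp(-12.5 * u^2) with u rising 0 -> 1.
    omega_max, ramp_tau : plateau value and ramp length (epochs) of the
        consistency-weight ramp-up omega(t) = omega_max * exp(-5 (1 - t/tau)^2).
    ensemble_alpha : temporal-ensembling constant alpha.
    supervised_norm : "labeled" divides L_c by |B ∩ L| (default), "batch"
        divides by |B|.
    """

    noise_sigma: float = 0.15
    lr_max: float = 5e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 50
    omega_max: float = 30.0
    ramp_tau: float = 30.0
    rampdown_constant: float = 12.5
    rampdown_length: int = 30
    ensemble_alpha: float = 0.6
    n_classes: int = 2
    supervised_norm: str = "labeled"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.ensemble_alpha < 1.0):
            raise ValueError("ensemble_alpha must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.supervised_norm not in ("labeled", "batch"):
            raise ValueError("supervised_norm must be 'labeled' or 'batch'")


@dataclass
class EnsembleState:
    """Per-sample ensemble predictions Z and bias-corrected targets Z~."""

    Z: np.ndarray        # (n_train, C), zeros at start
    epoch: int           # t, number of completed epochs (1-based after update)
    targets: np.ndarray  # (n_train, C) = Z / (1 - alpha^t)

    @staticmethod
    def initial(n_samples: int, n_classes: int) -> "EnsembleState":
        z = np.zeros((n_samples, n_classes))
        return EnsembleState(Z=z, epoch=0, targets=z.copy())


def augment(
    x: np.ndarray, sigma: float, rng: np.random.Generator, scale: float = 1.0
) -> np.ndarray:
    """x + i.i.d. zero-mean Gaussian noise of std ``sigma * scale``.

    ``scale`` is the per-subject robust amplitude reference (median absolute
    spectrogram value) so that sigma=0.15 is meaningful across subjects;
    sigma = 0 returns x unchanged (no rng draw).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return x
    return x + rng.normal(0.0, sigma * scale, size=x.shape)


def ramp_up_weight(t: float, omega_max: float = 30.0, tau: float = 30.0) -> float:
    """Consistency-loss weight omega(t): Gaussian ramp-up, then plateau.

    omega(t) = omega_max * exp(-5 (1 - t/tau)^2) for t <= tau, else omega_max.
    Continuous and nondecreasing; omega(0) = omega_max * e^-5.
    """
    if t < 0:
        raise ValueError("epoch must be >= 0")
    if t > tau:
        return float(omega_max)
    return float(omega_max * np.exp(-5.0 * (1.0 - t / tau) ** 2))


def update_ensemble(
    state: EnsembleState, epoch_predictions: np.ndarray, alpha: float
) -> EnsembleState:
    """Epoch-end temporal-ensembling update with startup-bias correction."""
    if state.Z.shape != epoch_predictions.shape:
        raise ValueError("prediction array shape does not match ensemble state")
    t = state.epoch + 1
    Z = alpha * state.Z + (1.0 - alpha) * epoch_predictions
    targets = Z / (1.0 - alpha ** t)
    return EnsembleState(Z=Z, epoch=t, targets=targets)


def supervised_loss(
    predictions: np.ndarray,
    labels: np.ndarray,
    labeled_mask: np.ndarray,
    norm: str = "labeled",
) -> tuple[float, np.ndarray]:
    """Cross-entropy over the labeled minibatch members; returns (loss, dL/dz).

    Uses the preictal probability z1 = predictions[:, 1]:
    -(y log z1 + (1-y) log(1-z1)), probabilities clipped to [1e-7, 1-1e-7].
    An all-unlabeled batch contributes 0 and a zero gradient.
    """
    grad = np.zeros_like(predictions)
    m = np.asarray(labeled_mask, dtype=bool)
    if not m.any():
        return 0.0, grad
    denom = int(m.sum()) if norm == "labeled" else predictions.shape[0]
    y = np.asarray(labels, dtype=float)[m]
    z1 = np.clip(predictions[m, 1], _EPS, 1.0 - _EPS)
    loss = float(np.sum(-(y * np.log(z1) + (1.0 - y) * np.log(1.0 - z1))) / denom)
    inside = (predictions[m, 1] > _EPS) & (predictions[m, 1] < 1.0 - _EPS)
    g1 = np.where(inside, (-(y / z1) + (1.0 - y) / (1.0 - z1)) / denom, 0.0)
    gm = np.zeros((int(m.sum()), predictions.shape[1]))
    gm[:, 1] = g1
    grad[m] = gm
    return loss, grad


def consistency_loss(
    predictions: np.ndarray, targets: np.ndarray, n_classes: int
) -> tuple[float, np.ndarray]:
    """Mean squared error to the ensemble targets; returns (loss, dL/dz).

    (1 / (C |B|)) * sum_i ||z_i - Z~_i||^2 over the whole minibatch.
    """
    diff = predictions - targets
    denom = n_classes * predictions.shape[0]
    loss = float(np.sum(diff * diff) / denom)
    return loss, 2.0 * diff / denom


def total_loss(l_sup: float, l_con: float, t: float,
               omega_max: float = 30.0, tau: float = 30.0) -> float:
    """Joint objective L = L_c + omega(t) * L_con."""
    return l_sup + ramp_up_weight(t, omega_max, tau) * l_con


def lr_schedule(t: int, cfg: TrainConfig) -> float:
    """Learning rate at 1-based epoch t: flat, then a time-reversed Gaussian
    ramp-down over the final ``rampdown_length`` epochs down to
    lr_max * exp(-rampdown_constant)."""
    if not (1 <= t <= cfg.max_epochs):
        raise ValueError("epoch out of range")
    start = cfg.max_epochs - cfg.rampdown_length
    if t <= start:
        return cfg.lr_max
    u = 1.0 - (cfg.max_epochs - t) / cfg.rampdown_length
    return float(cfg.lr_max * np.exp(-cfg.rampdown_constant * u * u))


@dataclass
class FitResult:
    """Outcome of a training run: best checkpoint and audit trail.

    ``weights`` is the checkpointed network state with the maximum validation
    accuracy (earliest epoch on ties); ``history`` has one record per epoch
    with L_c, L_con, omega, lr and validation accuracy; ``ensemble`` is the
    final temporal-ensembling state.
    """

    weights: list[np.ndarray]
    best_epoch: int
    best_val_accuracy: float
    history: list[dict]
    ensemble: EnsembleState
    model_config: ModelConfig
    train_config: TrainConfig
    input_shape: tuple[int, int, int]
    noise_scale: float

    def build_network(self) -> Sequential:
        """Rebuild the network and load the best checkpoint."""
        net = build_model(self.model_config, self.input_shape)
        net.set_weights(self.weights)
        return net

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        net = self.build_network()
        return net.forward(np.asarray(x, dtype=float), training=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def score(self, x: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(x) == np.asarray(y)).mean())

    def summary(self) -> str:
        lines = [
            "CSSPM fit result",
            "================",
            f"epochs run          : {len(self.history)}",
            f"best epoch          : {self.best_epoch}",
            f"best val accuracy   : {self.best_val_accuracy:.4f}",
            f"final L_c           : {self.history[-1]['loss_sup']:.4f}",
            f"final L_con         : {self.history[-1]['loss_con']:.4f}",
            f"ensemble epochs (t) : {self.ensemble.epoch}",
            f"noise scale         : {self.noise_scale:.4g}",
            "",
            "epoch    L_c     L_con   omega      lr     val_acc",
        ]
        for h in self.history:
            lines.append(
                f"{h['epoch']:5d}  {h['loss_sup']:6.4f}  {h['loss_con']:6.4f}"
                f"  {h['omega']:6.2f}  {h['lr']:.2e}  {h['val_accuracy']:.4f}"
            )
        return "\n".join(lines)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _check_finite(value: float, epoch: int, batch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite loss at epoch {epoch}, batch {batch}: {value!r}; "
            "check input scaling and learning rate"
        )


def _noise_scale(x: np.ndarray) -> float:
    s = float(np.median(np.abs(x)))
    return s if s > 0 else 1.0


def _run_training(
    x: np.ndarray,
    y: np.ndarray,
    labeled: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    use_consistency: bool,
) -> FitResult:
    cfg.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    labeled = np.asarray(labeled, dtype=bool)
    if not labeled.any():
        raise ValueError("training requires at least one labeled sample")
    if len(x_val) == 0:
        raise ValueError("validation set must be nonempty")

    n = x.shape[0]
    input_shape = x.shape[1:]
    net = build_model(model_cfg, input_shape, rng=_rng(cfg.seed, 17))
    opt = Adam(net, cfg.adam_beta1, cfg.adam_beta2)
    scale = _noise_scale(x)
    ens = EnsembleState.initial(n, cfg.n_classes)

    best_acc, best_epoch, best_weights = -np.inf, -1, None
    history: list[dict] = []

    for epoch in range(1, cfg.max_epochs + 1):
        order = _rng(cfg.seed, epoch).permutation(n)
        lr = lr_schedule(epoch, cfg)
        omega = ramp_up_weight(epoch, cfg.omega_max, cfg.ramp_tau) if use_consistency else 0.0
        epoch_preds = np.zeros((n, cfg.n_classes))
        sup_losses, con_losses = [], []

        for b, lo in enumerate(range(0, n, cfg.batch_size)):
            idx = order[lo : lo + cfg.batch_size]
            xb = augment(x[idx], cfg.noise_sigma, _rng(cfg.seed, epoch, b, 0), scale)
            z = net.forward(xb, training=True, rng=_rng(cfg.seed, epoch, b, 1))
            epoch_preds[idx] = z

            l_sup, g_sup = supervised_loss(z, y[idx], labeled[idx], cfg.supervised_norm)
            if use_consistency:
                l_con, g_con = consistency_loss(z, ens.targets[idx], cfg.n_classes)
                grad = g_sup + omega * g_con
            else:
                l_con, grad = 0.0, g_sup
            _check_finite(l_sup + omega * l_con, epoch, b)
            net.backward(grad)
            opt.step(lr)
            sup_losses.append(l_sup)
            con_losses.append(l_con)

        if use_consistency:
            ens = update_ensemble(ens, epoch_preds, cfg.ensemble_alpha)
        val_pred = net.forward(x_val, training=False).argmax(axis=1)
        val_acc = float((val_pred == y_val).mean())
        history.append({
            "epoch": epoch,
            "loss_sup": float(np.mean(sup_losses)),
            "loss_con": float(np.mean(con_losses)),
            "omega": omega,
            "lr": lr,
            "val_accuracy": val_acc,
        })
        if val_acc > best_acc:  # strict: ties keep the earliest epoch
            best_acc, best_epoch = val_acc, epoch
            best_weights = net.get_weights()

    return FitResult(
        weights=best_weights,
        best_epoch=best_epoch,
        best_val_accuracy=best_acc,
        history=history,
        ensemble=ens,
        model_config=model_cfg,
        train_config=cfg,
        input_shape=tuple(input_shape),
        noise_scale=scale,
    )


def fit(
    x: np.ndarray,
    y: np.ndarray,
    labeled: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
) -> FitResult:
    """Train CSSPM on ``x`` (labels ``y`` valid where ``labeled``)."""
    return _run_training(x, y, labeled, np.asarray(x_val, dtype=float),
                         np.asarray(y_val), model_cfg, cfg, use_consistency=True)


def fit_supervised(
    x: np.ndarray,
    y: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
) -> FitResult:
    """Plain supervised baseline: cross-entropy only, labeled data only.

    Consumes the same random streams as :func:`fit`, so CSSPM with
    ``omega_max = 0`` and no unlabeled samples reproduces this trajectory
    exactly under a shared seed.
    """
    labeled = np.ones(len(x), dtype=bool)
    return _run_training(np.asarray(x, dtype=float), y, labeled,
                         np.asarray(x_val, dtype=float), np.asarray(y_val),
                         model_cfg, cfg, use_consistency=False)


class CsspmClassifier:
    """Model object bundling data and configuration; ``fit()`` returns a
    :class:`FitResult`.

    Parameters
    ----------
    x, y, labeled : training spectrograms ``(n, ch, freq, time)``, labels
        (ignored where ``labeled`` is False) and the labeled mask.
    x_val, y_val : fully labeled validation samples.
    model_config, train_config : architecture and training hyperparameters.
    """

    def __init__(self, x, y, labeled, x_val, y_val,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None) -> None:
        self.x, self.y = x, y
        self.labeled = labeled
        self.x_val, self.y_val = x_val, y_val
        self.model_config = model_config or ModelConfig(n_channels=x.shape[1])
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_sample_sets(cls, train, validation,
                         model_config: ModelConfig | None = None,
                         train_config: TrainConfig | None = None):
        """Build from :class:`~csspm.preprocessing.SampleSet` objects."""
        if not validation.labeled.all():
            raise ValueError("validation samples must all be labeled")
        return cls(train.x, train.y, train.labeled, validation.x, validation.y,
                   model_config, train_config)

    def fit(self, supervised_only: bool = False) -> FitResult:
        if supervised_only:
            m = np.asarray(self.labeled, dtype=bool)
            return fit_supervised(self.x[m], np.asarray(self.y)[m],
                                  self.x_val, self.y_val,
                                  self.model_config, self.train_config)
        return fit(self.x, self.y, self.labeled, self.x_val, self.y_val,
                   self.model_config, self.train_config)
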