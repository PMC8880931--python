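"""Contrastive pre-training and the from-scratch supervised baseline.

Pre-training minimizes the batch NT-Xent loss with Adam; the learning
rate starts at ``initial_lr`` and decays once per epoch along a
half-period cosine, reaching zero at ``schedule_period`` epochs. The
cohort is split by patient (never by record) into 90% train / 10%
validation, and the checkpoint with the best validation loss is the one
returned.

The supervised baseline trains the same encoder plus a linear head from
random initialization, grid-searching learning rate x conv-layer
dropout with patience-5 early stopping per cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .architecture import (Encoder, EncoderConfig, ProjectionConfig,
                           ProjectionHead, build_encoder,
                           build_projection_head)
from .contrastive import LossConfig, batch_loss_and_grad
from .errors import DegenerateLabelsError, TrainingDivergedError, TrainingError
from .pairing import filter_eligible, sample_batches

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    initial_lr: float = 0.1
    schedule_period: int = 50
    seed: int = 0
    validation_fraction: float = 0.1
    batch_patients: int = 512
    schedule: str = "half_cosine"   # or "quarter_cosine" (non-vanishing)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.schedule not in ("half_cosine", "quarter_cosine"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass(frozen=True)
class ScratchConfig:
    lr_grid: tuple = (1e-2, 1e-3, 1e-4)
    dropout_grid: tuple = (0.0, 0.1, 0.2)
    early_stop_patience: int = 5
    max_epochs: int = 100
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if not self.lr_grid or not self.dropout_grid:
            raise ValueError("hyperparameter grids must be non-empty")


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Learning rate at the start of an epoch.

    half_cosine: lr = initial * (1 + cos(pi * epoch / period)) / 2,
    reaching 0 at epoch = period. Epochs beyond the period clamp to the
    final value (logged).
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    T = config.schedule_period
    if epoch > T:
        logger.warning("epoch %d beyond schedule period %d; clamping", epoch, T)
        epoch = T
    if config.schedule == "quarter_cosine":
        return config.initial_lr * math.cos(math.pi * epoch / (2 * T))
    return config.initial_lr * (1.0 + math.cos(math.pi * epoch / T)) / 2.0


def split_by_patient(groups, validation_fraction: float, seed: int) -> tuple:
    """Seeded patient-level train/validation split (no record leakage)."""
    rng = np.random.default_rng([seed, 915])
    perm = rng.permutation(len(groups))
    n_val = int(round(validation_fraction * len(groups)))
    val_idx = set(perm[:n_val].tolist())
    train = [g for i, g in enumerate(groups) if i not in val_idx]
    val = [g for i, g in enumerate(groups) if i in val_idx]
    if not val:
        raise TrainingError(
            f"validation split is empty ({len(groups)} patients at "
            f"fraction {validation_fraction})")
    if not train:
        raise TrainingError("training split is empty")
    return train, val


@dataclass
class PretrainResult:
    encoder: Encoder
    projection: ProjectionHead
    history: list            # per-epoch dicts: epoch, lr, train/val loss
    best_epoch: int
    best_val_loss: float


def _epoch_losses(groups, encoder, head, loss_config, seed, epoch,
                  batch_patients):
    """Mean per-pair validation loss in inference mode."""
    total, pairs = 0.0, 0
    n = min(batch_patients, len(groups))
    for batch in sample_batches(groups, n, seed=seed, epoch=epoch):
        H = encoder.forward(batch.stack(), training=False)
        Z = head.forward(H, training=False)
        loss, _ = batch_loss_and_grad(Z, batch.pair_index, loss_config)
        total += loss
        pairs += batch.n_patients
    return total / max(pairs, 1)


def pretrain(groups, encoder_config: EncoderConfig | None = None,
             projection_config: ProjectionConfig | None = None,
             loss_config: LossConfig | None = None,
             train_config: TrainConfig | None = None) -> PretrainResult:
    """Patient-contrastive pre-training on preprocessed tensor groups.

    ``groups`` is a sequence of per-patient tensor groups; single-record
    patients are filtered out here (they carry no positive pair). Fully
    reproducible from ``train_config.seed`` in single-threaded mode.
    """
    encoder_config = encoder_config or EncoderConfig()
    projection_config = projection_config or ProjectionConfig(
        hidden_units=encoder_config.representation_dim,
        output_units=encoder_config.representation_dim)
    loss_config = loss_config or LossConfig()
    cfg = train_config or TrainConfig()

    groups = filter_eligible(groups)
    if len(groups) < 2:
        raise TrainingError("need at least 2 eligible patients to pre-train")
    train_groups, val_groups = split_by_patient(
        groups, cfg.validation_fraction, cfg.seed)

    encoder = build_encoder(encoder_config, seed=cfg.seed)
    head = build_projection_head(
        projection_config, input_dim=encoder_config.representation_dim,
        seed=cfg.seed + 1)
    adam = _nn.Adam(encoder.params() + head.params())
    n_batch = min(cfg.batch_patients, len(train_groups))

    history = []
    best = (math.inf, -1, None)    # (val_loss, epoch, state)
    val_seed = cfg.seed + 7919     # separate stream for validation batches
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(epoch, cfg)
        total, pairs = 0.0, 0
        for batch in sample_batches(train_groups, n_batch, seed=cfg.seed,
                                    epoch=epoch):
            adam.zero_grad()
            X = batch.stack()
            H = encoder.forward(X, training=True)
            Z = head.forward(H, training=True)
            loss, dZ = batch_loss_and_grad(Z, batch.pair_index, loss_config)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (lr={lr:.4g}, "
                    f"|Z|max={np.abs(Z).max():.4g})")
            dH = head.backward(dZ)
            encoder.backward(dH)
            adam.step(lr)
            total += loss
            pairs += batch.n_patients
        train_loss = total / max(pairs, 1)
        val_loss = _epoch_losses(val_groups, encoder, head, loss_config,
                                 val_seed, epoch, cfg.batch_patients)
        history.append({"epoch": epoch, "lr": lr,
                        "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best[0]:
            best = (val_loss, epoch,
                    (encoder.get_state(), head.get_state()))

    encoder.set_state(best[2][0])
    head.set_state(best[2][1])
    return PretrainResult(encoder=encoder, projection=head, history=history,
                          best_epoch=best[1], best_val_loss=best[0])


# ---------------------------------------------------------------------------
# From-scratch supervised baseline.


class SupervisedModel:
    """Encoder + linear head: 2 softmax outputs (classification, trained
    with categorical cross-entropy) or 1 output (regression, MSE)."""

    def __init__(self, encoder_config: EncoderConfig, task: str,
                 dropout: float = 0.0, seed: int = 0):
        if task not in ("classification", "regression"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.encoder = build_encoder(encoder_config, seed=seed,
                                     dropout=dropout)
        n_out = 2 if task == "classification" else 1
        self.head = _nn.Dense(encoder_config.representation_dim, n_out,
                              rng=np.random.default_rng(seed + 1))

    def params(self):
        return self.encoder.params() + self.head.own_params()

    def get_state(self):
        return (self.encoder.get_state(), _nn.get_state(self.head))

    def set_state(self, state):
        self.encoder.set_state(state[0])
        _nn.set_state(self.head, state[1])

    def _forward(self, X, training):
        H = self.encoder.forward(X, training=training)
        return self.head.forward(H, training=training)

    def loss_and_grad(self, X, y, training=True):
        out = self._forward(X, training)
        n = out.shape[0]
        if self.task == "classification":
            logits = out - out.max(axis=1, keepdims=True)
            logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
            loss = -logp[np.arange(n), y].mean()
            dout = np.exp(logp)
            dout[np.arange(n), y] -= 1.0
            dout /= n
        else:
            resid = out[:, 0] - y
            loss = float(np.mean(resid ** 2))
            dout = (2.0 * resid / n)[:, None]
        return float(loss), dout

    def evaluate_loss(self, X, y) -> float:
        loss, _ = self.loss_and_grad(X, y, training=False)
        return loss

    def predict(self, X) -> np.ndarray:
        out = self._forward(np.asarray(X), training=False)
        if self.task == "classification":
            return out.argmax(axis=1)
        return out[:, 0]

    def predict_proba(self, X) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("probabilities only defined for classification")
        out = self._forward(np.asarray(X), training=False)
        logits = out - out.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class ScratchResult:
    model: SupervisedModel
    selected: dict            # {"lr": ..., "dropout": ...}
    best_val_loss: float
    cell_logs: list           # one dict per grid cell


def _train_one_cell(X_tr, y_tr, X_val, y_val, task, encoder_config, lr,
                    dropout, config: ScratchConfig):
    model = SupervisedModel(encoder_config, task, dropout=dropout,
                            seed=config.seed)
    adam = _nn.Adam(model.params())
    rng = np.random.default_rng([config.seed, 77])
    n = X_tr.shape[0]
    bs = min(config.batch_size, n)
    best_val, best_state, best_epoch = math.inf, None, -1
    epoch_log = []
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        for s in range(0, n, bs):
            idx = perm[s:s + bs]
            if idx.size < 2:
                continue            # BN needs >1 sample
            adam.zero_grad()
            loss, dout = model.loss_and_grad(X_tr[idx], y_tr[idx],
                                             training=True)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite scratch loss (lr={lr}, dropout={dropout})")
            dH = model.head.backward(dout)
            model.encoder.backward(dH)
            adam.step(lr)
        val_loss = model.evaluate_loss(X_val, y_val)
        epoch_log.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val, best_epoch = val_loss, epoch
            best_state = model.get_state()
        elif epoch - best_epoch >= config.early_stop_patience:
            break
    model.set_state(best_state)
    return model, best_val, epoch_log


def train_scratch(X_train, y_train, X_val, y_val, task: str,
                  encoder_config: EncoderConfig | None = None,
                  scratch_config: ScratchConfig | None = None) -> ScratchResult:
    """Grid-search supervised training from random initialization.

    Every (learning rate, dropout) cell trains with Adam and patience-5
    early stopping, restoring its best-validation checkpoint; the cell
    with the lowest validation loss wins.
    """
    encoder_config = encoder_config or EncoderConfig()
    config = scratch_config or ScratchConfig()
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    if task == "classification":
        y_train = np.asarray(y_train, dtype=int)
        y_val = np.asarray(y_val, dtype=int)
        if np.unique(y_train).size < 2:
            raise DegenerateLabelsError(
                "classification labels contain a single class")
    else:
        y_train = np.asarray(y_train, dtype=np.float64)
        y_val = np.asarray(y_val, dtype=np.float64)

    best = None
    cell_logs = []
    for lr in config.lr_grid:
        for dropout in config.dropout_grid:
            model, val_loss, log = _train_one_cell(
                X_train, y_train, X_val, y_val, task, encoder_config,
                lr, dropout, config)
            cell_logs.append({"lr": lr, "dropout": dropout,
                              "best_val_loss": val_loss,
                              "val_loss_per_epoch": log})
            if best is None or val_loss < best[1]:
                best = (model, val_loss, {"lr": lr, "dropout": dropout})
    return ScratchResult(model=best[0], selected=best[2],
                         best_val_loss=best[1], cell_logs=cell_logs)
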