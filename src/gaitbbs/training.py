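"""Training protocol: Adam on MSE, early stopping, 5-fold cross-validation.

The network is trained per-window against the subject's normalized BBS
total (MSE loss, Adam, learning rate 0.001, batch size 64, up to 200
epochs). Early stopping watches the validation loss with a patience of 20
epochs — a strict decrease counts as improvement, ties do not — and
restores the weights of the best epoch; when stopping triggers, the best
epoch is exactly ``stop_epoch - patience``.

Cross-validation rotates five folds; metrics are computed on each held-out
fold after mapping predictions back to the 0-56 scale so MAE/RMSE are in
clinically interpretable BBS points. Two split granularities exist:
``segment`` shuffles windows (the arithmetic of a 4800-window dataset:
960-window folds, 3840-window training splits) and ``subject`` keeps all
of a subject's windows in one fold, avoiding identity leakage across
folds at the cost of lumpier fold sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .evaluation import mae, rmse
from .errors import ConfigError
from .model import BbsNet, ModelConfig, build_network
from .preprocessing import GaitDataset, denormalize_score

__all__ = [
    "TrainConfig",
    "FoldRecord",
    "CVResult",
    "EarlyStopper",
    "run_early_stopping",
    "make_folds",
    "fit_one_fold",
    "cross_validate",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    n_folds: int = 5
    split_mode: str = "segment"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if not 0 < self.patience < self.max_epochs:
            raise ConfigError("need 0 < patience < max_epochs")
        if self.split_mode not in ("segment", "subject"):
            raise ConfigError(f"unknown split_mode {self.split_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldRecord:
    mae: float
    rmse: float
    best_epoch: int
    stop_epoch: int
    train_loss: list[float]
    val_loss: list[float]


@dataclass
class CVResult:
    per_fold: list[FoldRecord]
    mean_mae: float
    mean_rmse: float

    def to_dict(self) -> dict:
        return {"per_fold": [asdict(f) for f in self.per_fold],
                "mean_mae": self.mean_mae, "mean_rmse": self.mean_rmse}


class EarlyStopper:
    """Patience-based stopping on validation loss, strict-decrease rule."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.wait = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record epoch ``epoch`` (1-based); return True if training should stop."""
        if loss < self.best:
            self.best, self.best_epoch, self.wait = loss, epoch, 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def run_early_stopping(val_losses: list[float], patience: int) -> tuple[int, int]:
    """Apply the stopping rule to a loss trace; returns (stop_epoch, best_epoch).

    Pure bookkeeping: a trace whose last improvement is at epoch 167 stops
    at epoch 187 under patience 20 and reports best epoch 167.
    """
    stopper = EarlyStopper(patience)
    for epoch, loss in enumerate(val_losses, start=1):
        if stopper.update(epoch, loss):
            return epoch, stopper.best_epoch
    return len(val_losses), stopper.best_epoch


def make_folds(dataset: GaitDataset, cfg: TrainConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint (train_idx, test_idx) pairs covering the dataset.

    ``segment`` mode shuffles window indices; ``subject`` mode assigns whole
    subjects to folds so no subject spans folds.
    """
    n = len(dataset)
    if n < cfg.n_folds:
        raise ConfigError(f"dataset of {n} segments cannot be split into {cfg.n_folds} folds")
    rng = np.random.default_rng(cfg.seed)
    if cfg.split_mode == "segment":
        perm = rng.permutation(n)
        test_sets = np.array_split(perm, cfg.n_folds)
    else:
        subjects = list(dict.fromkeys(dataset.subject_ids.tolist()))  # first-appearance order
        if len(subjects) < cfg.n_folds:
            raise ConfigError(
                f"subject mode needs >= {cfg.n_folds} subjects, got {len(subjects)}")
        order = rng.permutation(len(subjects))
        groups = np.array_split(np.array(subjects, dtype=object)[order], cfg.n_folds)
        test_sets = [np.flatnonzero(np.isin(dataset.subject_ids, list(g))) for g in groups]
    folds = []
    for test in test_sets:
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        folds.append((np.flatnonzero(mask), np.asarray(test)))
    return folds


def _mse_eval(net: BbsNet, X: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
    pred = net.predict(X, batch_size=batch)
    return float(np.mean((pred - y) ** 2))


def fit_one_fold(train_data: tuple[np.ndarray, np.ndarray],
                 val_data: tuple[np.ndarray, np.ndarray],
                 model_cfg: ModelConfig, train_cfg: TrainConfig,
                 net: BbsNet | None = None) -> tuple[BbsNet, FoldRecord]:
    """Train one model with minibatch Adam + early stopping; restore best weights."""
    Xtr, ytr = train_data
    Xva, yva = val_data
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ConfigError("train and validation sets must be non-empty")
    if net is None:
        net = build_network(model_cfg, seed=train_cfg.seed)
    opt = net.make_optimizer(lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed + 1)
    stopper = EarlyStopper(train_cfg.patience)
    best_state = net.snapshot()
    train_hist: list[float] = []
    val_hist: list[float] = []
    stop_epoch = train_cfg.max_epochs
    B = train_cfg.batch_size
    for epoch in range(1, train_cfg.max_epochs + 1):
        perm = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for i in range(0, len(perm), B):
            idx = perm[i:i + B]
            xb, yb = Xtr[idx], ytr[idx]
            pred = net.forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            net.backward(2.0 * err / len(idx))
            opt.step()
            epoch_loss += loss * len(idx)
        train_hist.append(epoch_loss / len(perm))
        val_loss = _mse_eval(net, Xva, yva)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        val_hist.append(val_loss)
        improved = val_loss < stopper.best
        should_stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = net.snapshot()
        if should_stop:
            stop_epoch = epoch
            break
    net.load_state_dict(best_state)
    val_pred_bbs = denormalize_score(np.clip(net.predict(Xva), 0.0, 1.0))
    val_true_bbs = denormalize_score(yva)
    record = FoldRecord(
        mae=mae(val_true_bbs, val_pred_bbs),
        rmse=rmse(val_true_bbs, val_pred_bbs),
        best_epoch=stopper.best_epoch,
        stop_epoch=stop_epoch,
        train_loss=train_hist,
        val_loss=val_hist,
    )
    return net, record


def cross_validate(dataset: GaitDataset, model_cfg: ModelConfig,
                   train_cfg: TrainConfig,
                   folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
                   return_models: bool = False):
    """K-fold protocol; fold metrics are MAE/RMSE in BBS points (0-56 scale)."""
    if folds is None:
        folds = make_folds(dataset, train_cfg)
    records: list[FoldRecord] = []
    models: list[BbsNet] = []
    for k, (train_idx, test_idx) in enumerate(folds):
        try:
            net, rec = fit_one_fold(
                (dataset.X[train_idx], dataset.y[train_idx]),
                (dataset.X[test_idx], dataset.y[test_idx]),
                model_cfg, train_cfg)
        except Exception as exc:
            raise type(exc)(f"fold {k}: {exc}") from exc
        records.append(rec)
        if return_models:
            models.append(net)
    result = CVResult(
        per_fold=records,
        mean_mae=float(np.mean([r.mae for r in records])),
        mean_rmse=float(np.mean([r.rmse for r in records])),
    )
    return (result, models) if return_models else result
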