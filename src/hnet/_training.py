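"""Shared fitting machinery: scaling, configuration and the training loop.

HNet and its S-learner ablation share this code path deliberately, so that
benchmark differences between them reflect the architectural mechanism
(hypernetwork vs. plain head) and not incidental training choices.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from ._nn import Adam
from .exceptions import DataError, ShapeError, TrainingError

__all__ = ["TrainConfig", "Scaler", "train_core"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters shared by all estimators in the package.

    Defaults target the small-tabular regime (a few hundred to a few
    thousand rows): minibatch Adam at 1e-3 with decoupled weight decay and
    a cosine-decayed learning rate over a fixed 400-epoch schedule; a 10%
    validation split is held out to pick the best EMA snapshot and the best
    of ``n_restarts`` independent initializations.  ``patience=None`` means
    the full schedule always runs (no early stop).
    """

    learning_rate: float = 1e-3
    weight_decay: float = 0.1
    max_epochs: int = 400
    batch_size: int | None = 64
    val_fraction: float = 0.1
    patience: int | None = None
    n_restarts: int = 2
    activation: str = "elu"
    representation_dim: int = 8
    encoder_widths: tuple[int, ...] = (64,)
    hyper_widths: tuple[int, ...] = (32,)
    target_hidden: tuple[int, ...] = (16,)
    head_widths: tuple[int, ...] = (48, 48)
    hyper_output_scale: float = 0.1
    ema_decay: float | None = 0.995  # None disables parameter averaging
    lr_decay: bool = True  # cosine decay of the learning rate to lr/10
    raw_covariates: bool = False  # S-learner only: feed X instead of Z to the head


@dataclass(frozen=True)
class Scaler:
    """Affine input/output maps fitted on training data only.

    Covariates and treatments are min-max mapped onto [0, 1] (constant
    covariate columns dropped with a warning) and the outcome is z-scored;
    predictions are mapped back to outcome units on the way out.  Keeping
    covariates and treatment on a common unit scale matters: standardizing
    covariates to unit variance inflates their scale relative to the
    treatment input and measurably biases fits toward covariate-only
    structure (the flat-dose-response failure mode).
    """

    keep: np.ndarray          # boolean mask over covariate columns
    x_min: np.ndarray
    x_max: np.ndarray
    t_min: np.ndarray
    t_max: np.ndarray
    y_mean: float
    y_std: float

    @classmethod
    def fit(cls, X: np.ndarray, T: np.ndarray, Y: np.ndarray) -> "Scaler":
        X = np.asarray(X, float)
        T = np.asarray(T, float)
        Y = np.asarray(Y, float)
        x_min = X.min(axis=0)
        x_max = X.max(axis=0)
        keep = x_max - x_min > 0
        if not keep.any():
            raise DataError("all covariate columns are constant")
        if not keep.all():
            dropped = np.flatnonzero(~keep).tolist()
            warnings.warn(
                f"dropping constant covariate column(s) {dropped} before scaling",
                stacklevel=3,
            )
        t_min = T.min(axis=0)
        t_max = T.max(axis=0)
        if np.any(t_max - t_min <= 0):
            raise DataError("treatment has zero range; cannot normalize")
        y_std = float(Y.std())
        return cls(
            keep=keep,
            x_min=x_min[keep],
            x_max=x_max[keep],
            t_min=t_min,
            t_max=t_max,
            y_mean=float(Y.mean()),
            y_std=y_std if y_std > 0 else 1.0,
        )

    @property
    def p_in(self) -> int:
        return self.keep.size

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.keep.size:
            raise ShapeError(f"expected {self.keep.size} covariates, got {X.shape[1]}")
        return (X[:, self.keep] - self.x_min) / (self.x_max - self.x_min)

    def transform_t(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, float)
        if T.ndim == 1:
            T = T[:, None]
        if T.shape[1] != self.t_min.size:
            raise ShapeError(f"expected {self.t_min.size} treatment column(s), got {T.shape[1]}")
        return (T - self.t_min) / (self.t_max - self.t_min)

    def transform_y(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, float) - self.y_mean) / self.y_std

    def inverse_y(self, Ys: np.ndarray) -> np.ndarray:
        return np.asarray(Ys, float) * self.y_std + self.y_mean


class ModelCore(Protocol):
    """A differentiable predictor trained by :func:`train_core`."""

    def params(self) -> list[np.ndarray]: ...

    def forward(self, X: np.ndarray, T: np.ndarray,
                cache: dict | None = None) -> np.ndarray: ...

    def backward(self, cache: dict, g_pred: np.ndarray) -> list[np.ndarray]: ...


def train_core(core: ModelCore, X: np.ndarray, T: np.ndarray, Y: np.ndarray,
               cfg: TrainConfig, seed_seq: np.random.SeedSequence) -> dict:
    """Fit ``core`` by MSE with Adam, early stopping on a validation split.

    The parameters kept at the end are an exponential moving average (EMA)
    of the optimization trajectory (decay ``cfg.ema_decay``), snapshotted at
    the epoch where the EMA model's validation loss is lowest: minibatch
    noise makes the instantaneous iterates' counterfactual curves wobble
    epoch to epoch, and averaging removes most of that variance.

    All randomness (validation split, shuffling) derives from ``seed_seq``.
    Returns a history dict with initial/final training loss and the epoch
    count actually run.  Raises :class:`TrainingError` on divergence.
    """
    n = Y.shape[0]
    rng_split, rng_shuffle = (np.random.default_rng(s) for s in seed_seq.spawn(2))

    n_val = int(round(cfg.val_fraction * n))
    if n - n_val < 2:
        n_val = 0
    perm = rng_split.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    monitor_idx = val_idx if n_val > 0 else tr_idx

    batch = min(cfg.batch_size or 64, tr_idx.size)
    params = core.params()
    opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    ema = [p.copy() for p in params] if cfg.ema_decay is not None else None

    def loss_on(idx: np.ndarray) -> float:
        pred = core.forward(X[idx], T[idx])
        return float(np.mean((pred - Y[idx]) ** 2))

    initial_loss = loss_on(tr_idx)
    best = np.inf
    best_params = [p.copy() for p in params]
    best_epoch = -1
    since_best = 0
    epochs_run = 0

    def swap_in(source):
        for p, src in zip(params, source):
            tmp = p.copy()
            np.copyto(p, src)
            np.copyto(src, tmp)

    for epoch in range(cfg.max_epochs):
        if cfg.lr_decay:
            frac = epoch / max(cfg.max_epochs - 1, 1)
            opt.lr = cfg.learning_rate * (0.55 + 0.45 * np.cos(np.pi * frac))
        order = rng_shuffle.permutation(tr_idx.size)
        for start in range(0, tr_idx.size, batch):
            idx = tr_idx[order[start:start + batch]]
            cache: dict = {}
            pred = core.forward(X[idx], T[idx], cache)
            resid = pred - Y[idx]
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            grads = core.backward(cache, (2.0 / idx.size) * resid)
            opt.step(params, grads)
            if ema is not None:
                d = cfg.ema_decay
                for e, p in zip(ema, params):
                    e *= d
                    e += (1.0 - d) * p
        epochs_run = epoch + 1
        if ema is not None:
            swap_in(ema)  # monitor the averaged model
        mloss = loss_on(monitor_idx)
        if not np.isfinite(mloss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        if mloss < best:
            best = mloss
            best_epoch = epoch
            for bp, p in zip(best_params, params):
                np.copyto(bp, p)
            since_best = 0
        else:
            since_best += 1
        if ema is not None:
            swap_in(ema)  # restore live iterates
        if cfg.patience is not None and since_best > cfg.patience:
            break

    for p, bp in zip(params, best_params):
        np.copyto(p, bp)
    return {
        "initial_train_loss": initial_loss,
        "final_train_loss": loss_on(tr_idx),
        "best_monitor_loss": best,
        "best_epoch": best_epoch,
        "epochs_run": epochs_run,
        "n_val": int(n_val),
    }
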