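"""Neural S-learner ablation baseline.

Same encoder capacity and training loop as the hypernetwork estimator, but
the hypernetwork mechanism is replaced by a plain multilayer perceptron
head that consumes the concatenation of the learned representation and the
treatment value.  Comparing the two on matched replicates isolates the
value of generating per-instance dose-response weights.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import DenseMLP
from ._training import Scaler, TrainConfig, train_core
from .data_model import DoseGrid, ObservationalDataset
from .exceptions import ExtrapolationWarning, ShapeError
from .hypernet import _overshoot_penalty

__all__ = ["SLearnerModel", "fit_slearner", "predict_curve_slearner"]


class _SLearnerCore:
    """Encoder + concat(Z, T) head; ``encoder=None`` feeds raw covariates."""

    def __init__(self, encoder: DenseMLP | None, head: DenseMLP):
        self.encoder = encoder
        self.head = head

    def params(self) -> list[np.ndarray]:
        enc = self.encoder.params() if self.encoder is not None else []
        return enc + self.head.params()

    def representation(self, Xs: np.ndarray) -> np.ndarray:
        return Xs if self.encoder is None else self.encoder.forward(Xs)

    def forward(self, Xs: np.ndarray, Ts: np.ndarray,
                cache: dict | None = None) -> np.ndarray:
        c_enc: list | None = [] if cache is not None else None
        c_head: list | None = [] if cache is not None else None
        z = Xs if self.encoder is None else self.encoder.forward(Xs, c_enc)
        h = np.concatenate([z, Ts], axis=1)
        pred = self.head.forward(h, c_head)[:, 0]
        if cache is not None:
            cache.update(enc=c_enc, head=c_head, k=z.shape[1])
        return pred

    def backward(self, cache: dict, g_pred: np.ndarray) -> list[np.ndarray]:
        g_h, g_head = self.head.backward(cache["head"], np.asarray(g_pred)[:, None])
        if self.encoder is None:
            return g_head
        _, g_enc = self.encoder.backward(cache["enc"], g_h[:, :cache["k"]])
        return g_enc + g_head


@dataclass
class SLearnerModel:
    """A fitted neural S-learner (treatment as an ordinary input feature)."""

    encoder: DenseMLP | None
    head: DenseMLP
    tau: int
    scaler: Scaler
    config: TrainConfig
    seed: int
    history: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.scaler.p_in

    @property
    def n_params(self) -> int:
        enc = self.encoder.n_params if self.encoder is not None else 0
        return enc + self.head.n_params

    @property
    def _core(self) -> _SLearnerCore:
        return _SLearnerCore(self.encoder, self.head)

    def forward_batch(self, X: np.ndarray, T: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform_x(np.atleast_2d(X))
        Ts = self.scaler.transform_t(T)
        if Xs.shape[0] != Ts.shape[0]:
            raise ShapeError(f"X has {Xs.shape[0]} rows but T has {Ts.shape[0]}")
        return self.scaler.inverse_y(self._core.forward(Xs, Ts))

    def predict_curve(self, x: np.ndarray, grid: DoseGrid) -> np.ndarray:
        """Dose-response curve for one row; the representation is computed
        once and broadcast across the grid."""
        return self.predict_curves(np.atleast_2d(x), grid)[0]

    def predict_curves(self, X: np.ndarray, grid: DoseGrid) -> np.ndarray:
        rng_ = self.scaler.t_max[0] - self.scaler.t_min[0]
        lo = self.scaler.t_min[0] - 0.05 * rng_
        hi = self.scaler.t_max[0] + 0.05 * rng_
        if grid.points.min() < lo or grid.points.max() > hi:
            warnings.warn(
                "dose grid extends beyond the fitted treatment support; "
                "curve values are extrapolations",
                ExtrapolationWarning, stacklevel=2,
            )
        Xs = self.scaler.transform_x(np.atleast_2d(X))
        z = self._core.representation(Xs)  # computed once per row
        ts = self.scaler.transform_t(grid.points[:, None])[:, 0]
        n, g = z.shape[0], ts.size
        z_rep = np.repeat(z, g, axis=0)
        t_rep = np.tile(ts, n)[:, None]
        h = np.concatenate([z_rep, t_rep], axis=1)
        pred = self.head.forward(h)[:, 0].reshape(n, g)
        return self.scaler.inverse_y(pred)

    def contrast(self, x: np.ndarray, t_a: float, t_b: float) -> float:
        x = np.atleast_2d(x)
        ta = np.full((1, self.tau), t_a, dtype=float)
        tb = np.full((1, self.tau), t_b, dtype=float)
        return float(self.forward_batch(x, ta)[0] - self.forward_batch(x, tb)[0])

    def save(self, path) -> None:
        """Serialize to a single .npz archive (spec JSON + flat arrays)."""
        meta = {
            "kind": "slearner",
            "tau": self.tau,
            "encoder_dims": self.encoder.dims if self.encoder is not None else None,
            "head_dims": self.head.dims,
            "activation": self.head.activation,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
            "seed": self.seed,
            "history": self.history,
        }
        arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        sc = self.scaler
        arrays.update(
            scaler_keep=sc.keep, scaler_x_min=sc.x_min, scaler_x_max=sc.x_max,
            scaler_t_min=sc.t_min, scaler_t_max=sc.t_max,
            scaler_y=np.array([sc.y_mean, sc.y_std]),
        )
        if self.encoder is not None:
            for i, arr in enumerate(self.encoder.params()):
                arrays[f"enc_{i}"] = arr
        for i, arr in enumerate(self.head.params()):
            arrays[f"head_{i}"] = arr
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path) -> "SLearnerModel":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            if meta.get("kind") != "slearner":
                raise ValueError(f"{path} does not contain an S-learner model")
            cfg = TrainConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                 for k, v in meta["config"].items()})
            rng = np.random.default_rng(0)
            encoder = None
            if meta["encoder_dims"] is not None:
                encoder = DenseMLP(meta["encoder_dims"], meta["activation"], rng=rng)
                for i, arr in enumerate(encoder.params()):
                    np.copyto(arr, z[f"enc_{i}"])
            head = DenseMLP(meta["head_dims"], meta["activation"], rng=rng)
            for i, arr in enumerate(head.params()):
                np.copyto(arr, z[f"head_{i}"])
            scaler = Scaler(
                keep=z["scaler_keep"].astype(bool),
                x_min=z["scaler_x_min"], x_max=z["scaler_x_max"],
                t_min=z["scaler_t_min"], t_max=z["scaler_t_max"],
                y_mean=float(z["scaler_y"][0]), y_std=float(z["scaler_y"][1]),
            )
        return cls(encoder=encoder, head=head, tau=meta["tau"], scaler=scaler,
                   config=cfg, seed=meta["seed"], history=meta["history"])


def fit_slearner(train: ObservationalDataset, config: TrainConfig | None = None,
                 seed: int = 0) -> SLearnerModel:
    """Train the S-learner ablation with the same optimizer defaults as HNet.

    With ``config.raw_covariates=True`` the head consumes (X, T) directly
    and no encoder is trained.
    """
    cfg = config or TrainConfig()
    scaler = Scaler.fit(train.X, train.T, train.Y)
    Xs = scaler.transform_x(train.X)
    Ts = scaler.transform_t(train.T)
    Ys = scaler.transform_y(train.Y)

    best: SLearnerModel | None = None
    for ss in np.random.SeedSequence(seed).spawn(max(cfg.n_restarts, 1)):
        ss_init, ss_train = ss.spawn(2)
        rng = np.random.default_rng(ss_init)
        if cfg.raw_covariates:
            encoder = None
            k = Xs.shape[1]
        else:
            encoder = DenseMLP([Xs.shape[1], *cfg.encoder_widths, cfg.representation_dim],
                               cfg.activation, rng=rng)
            k = cfg.representation_dim
        head = DenseMLP([k + train.tau, *cfg.head_widths, 1], cfg.activation, rng=rng)

        core = _SLearnerCore(encoder, head)
        history = train_core(core, Xs, Ts, Ys, cfg, ss_train)
        if train.tau == 1:
            z = core.representation(Xs[:128])
            ts = np.linspace(0.0, 1.0, 33)
            h = np.concatenate([np.repeat(z, ts.size, axis=0),
                                np.tile(ts, z.shape[0])[:, None]], axis=1)
            penalty = _overshoot_penalty(head.forward(h)[:, 0])
        else:
            penalty = 0.0
        history["selection_loss"] = history["best_monitor_loss"] + penalty
        model = SLearnerModel(encoder=encoder, head=head, tau=train.tau,
                              scaler=scaler, config=cfg, seed=seed, history=history)
        if best is None or (history["selection_loss"]
                            < best.history["selection_loss"]):
            best = model
    return best


def predict_curve_slearner(model: SLearnerModel, x: np.ndarray,
                           grid: DoseGrid) -> np.ndarray:
    """Functional alias for :meth:`SLearnerModel.predict_curve`."""
    return model.predict_curve(x, grid)
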