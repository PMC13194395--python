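"""The hypernetwork dose-response estimator.

An encoder ``f_phi: R^p -> R^k`` maps covariates to a representation ``z``;
a hypernetwork ``g_psi: R^k -> R^m`` maps ``z`` to the full flat weight
vector ``omega`` of a small *fixed-architecture* target network
``h_omega: R^tau -> R`` that takes the treatment as its only input and
returns the predicted outcome:

    y_hat = h_{g_psi(f_phi(x))}(t)

The composite is trained end-to-end by outcome mean squared error, so the
gradient flows through the generated weights.  Because the treatment enters
only through its own dedicated network, the model cannot bury the treatment
signal inside a high-dimensional representation — the inductive bias that
separates it from an S-learner.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import DenseMLP, get_activation
from ._training import Scaler, TrainConfig, train_core
from .data_model import DoseGrid, ObservationalDataset
from .exceptions import ExtrapolationWarning, ShapeError

__all__ = [
    "TargetNetSpec",
    "HNetModel",
    "target_param_count",
    "pack_weights",
    "unpack_weights",
    "apply_target_network",
    "fit",
    "forward_batch",
    "mse_loss",
]

#: relative slack, as a fraction of the fitted treatment range, before a
#: dose grid is flagged as extrapolating beyond the training support
_SUPPORT_SLACK = 0.05


@dataclass(frozen=True)
class TargetNetSpec:
    """Fixed architecture of the per-instance target network ``h_omega``.

    ``input_dim`` is the treatment dimensionality tau; ``hidden_widths`` may
    be empty, in which case the network is affine.  The output is always a
    single scalar.  The total scalar parameter count ``m`` (weights plus
    biases over all layers) follows from the widths in closed form.
    """

    input_dim: int = 1
    hidden_widths: tuple[int, ...] = (32,)
    activation: str = "elu"

    def __post_init__(self):
        object.__setattr__(self, "hidden_widths", tuple(int(w) for w in self.hidden_widths))
        if self.input_dim < 1:
            raise ValueError(f"input_dim must be >= 1, got {self.input_dim}")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError(f"hidden widths must be >= 1, got {self.hidden_widths}")
        get_activation(self.activation)  # validates the name

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_widths, 1)

    @property
    def param_count(self) -> int:
        dims = self.layer_dims
        return sum(fi * fo + fo for fi, fo in zip(dims[:-1], dims[1:]))


def target_param_count(spec: TargetNetSpec) -> int:
    """Total scalar parameter count m = sum(fan_in*fan_out + fan_out)."""
    return spec.param_count


def unpack_weights(omega: np.ndarray, spec: TargetNetSpec
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a flat weight vector into per-layer ``(W, b)`` pairs.

    Layout (documented and fixed): layers in input-to-output order; within a
    layer, the weight matrix ``W`` of shape (fan_out, fan_in) flattened
    row-major, followed by the bias vector of length fan_out.  A leading
    batch axis on ``omega`` is carried through.
    """
    omega = np.asarray(omega, dtype=float)
    m = spec.param_count
    if omega.shape[-1] != m:
        raise ShapeError(
            f"expected weight vector of length m={m} for spec {spec.layer_dims}, "
            f"got {omega.shape[-1]}"
        )
    dims = spec.layer_dims
    layers = []
    pos = 0
    for fi, fo in zip(dims[:-1], dims[1:]):
        w = omega[..., pos:pos + fi * fo].reshape(*omega.shape[:-1], fo, fi)
        pos += fi * fo
        b = omega[..., pos:pos + fo]
        pos += fo
        layers.append((w, b))
    return layers


def pack_weights(layers: list[tuple[np.ndarray, np.ndarray]],
                 spec: TargetNetSpec) -> np.ndarray:
    """Inverse of :func:`unpack_weights` (exact bijection)."""
    pieces = []
    for w, b in layers:
        w = np.asarray(w, dtype=float)
        pieces.append(w.reshape(*w.shape[:-2], -1))
        pieces.append(np.asarray(b, dtype=float))
    omega = np.concatenate(pieces, axis=-1)
    if omega.shape[-1] != spec.param_count:
        raise ShapeError(
            f"packed length {omega.shape[-1]} != m={spec.param_count}"
        )
    return omega


def _target_forward(omega: np.ndarray, T: np.ndarray, spec: TargetNetSpec,
                    cache: list | None = None) -> np.ndarray:
    """Evaluate h_omega with per-row weights: omega (n, m), T (n, tau) -> (n,)."""
    act, _ = get_activation(spec.activation)
    layers = unpack_weights(omega, spec)
    a = np.asarray(T, dtype=float)
    if a.shape[1] != spec.input_dim:
        raise ShapeError(f"expected tau={spec.input_dim} treatment columns, got {a.shape[1]}")
    last = len(layers) - 1
    for i, (w, b) in enumerate(layers):
        u = np.einsum("nof,nf->no", w, a) + b
        if cache is not None:
            cache.append((a, u, w))
        a = act(u) if i < last else u
    return a[:, 0]


def _target_backward(cache: list, g_pred: np.ndarray, spec: TargetNetSpec
                     ) -> np.ndarray:
    """Gradient of the per-row output w.r.t. the flat weight vector omega.

    Returns (n, m) aligned with the :func:`unpack_weights` layout.
    """
    _, act_grad = get_activation(spec.activation)
    last = len(cache) - 1
    g = np.asarray(g_pred, dtype=float)[:, None]  # (n, 1)
    layer_grads: list[np.ndarray | None] = [None] * len(cache)
    for i in range(last, -1, -1):
        a_prev, u, w = cache[i]
        if i < last:
            g = g * act_grad(u)
        g_w = np.einsum("no,nf->nof", g, a_prev)
        g_b = g
        layer_grads[i] = np.concatenate(
            [g_w.reshape(g_w.shape[0], -1), g_b], axis=1
        )
        g = np.einsum("nof,no->nf", w, g)
    return np.concatenate(layer_grads, axis=1)  # type: ignore[arg-type]


def _target_curves(omega: np.ndarray, t_grid: np.ndarray, spec: TargetNetSpec
                   ) -> np.ndarray:
    """Evaluate each row's generated network on a shared scalar dose grid.

    omega (n, m), t_grid (G,) -> (n, G).  The weights are generated once per
    row and reused across the whole grid.
    """
    if spec.input_dim != 1:
        raise ShapeError("dose grids are defined for scalar treatments (tau=1)")
    act, _ = get_activation(spec.activation)
    layers = unpack_weights(omega, spec)
    n, g_pts = omega.shape[0], np.asarray(t_grid, dtype=float)
    a = np.broadcast_to(g_pts[None, :, None], (n, g_pts.size, 1))
    last = len(layers) - 1
    for i, (w, b) in enumerate(layers):
        u = np.einsum("nof,ngf->ngo", w, a) + b[:, None, :]
        a = act(u) if i < last else u
    return a[..., 0]


def apply_target_network(omega: np.ndarray, t, spec: TargetNetSpec) -> float:
    """Feed-forward evaluation of one generated network at one treatment row."""
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 1:
        raise ShapeError("apply_target_network expects a single flat weight vector")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.shape != (spec.input_dim,):
        raise ShapeError(f"expected a treatment row with tau={spec.input_dim} entries")
    return float(_target_forward(omega[None, :], t[None, :], spec)[0])


class _HNetCore:
    """Encoder + hypernetwork + generated target net with chained backprop."""

    def __init__(self, encoder: DenseMLP, hyper: DenseMLP, spec: TargetNetSpec):
        self.encoder = encoder
        self.hyper = hyper
        self.spec = spec

    def params(self) -> list[np.ndarray]:
        return self.encoder.params() + self.hyper.params()

    def omega(self, Xs: np.ndarray) -> np.ndarray:
        return self.hyper.forward(self.encoder.forward(Xs))

    def forward(self, Xs: np.ndarray, Ts: np.ndarray,
                cache: dict | None = None) -> np.ndarray:
        c_enc: list | None = [] if cache is not None else None
        c_hyp: list | None = [] if cache is not None else None
        c_tgt: list | None = [] if cache is not None else None
        z = self.encoder.forward(Xs, c_enc)
        omega = self.hyper.forward(z, c_hyp)
        pred = _target_forward(omega, Ts, self.spec, c_tgt)
        if cache is not None:
            cache.update(enc=c_enc, hyp=c_hyp, tgt=c_tgt)
        return pred

    def backward(self, cache: dict, g_pred: np.ndarray) -> list[np.ndarray]:
        g_omega = _target_backward(cache["tgt"], g_pred, self.spec)
        g_z, g_hyp = self.hyper.backward(cache["hyp"], g_omega)
        _, g_enc = self.encoder.backward(cache["enc"], g_z)
        return g_enc + g_hyp


def _stabilize_hyper_output(hyper: DenseMLP, spec: TargetNetSpec,
                            scale: float, rng: np.random.Generator) -> None:
    """Re-initialize the hypernetwork's output layer so the *generated*
    weights start near a standard fan-in initialization of the target net.

    The output layer's weights are shrunk by ``scale`` and its bias is set to
    one concrete fan-in draw of the target network; generated weight vectors
    then begin as that draw plus small instance-specific perturbations.
    Without this, generated weights start an order of magnitude too large
    and training is unstable.
    """
    hyper.weights[-1] *= scale
    dims = spec.layer_dims
    layers = []
    for fi, fo in zip(dims[:-1], dims[1:]):
        layers.append((rng.normal(0.0, 1.0 / np.sqrt(fi), size=(fo, fi)),
                       np.zeros(fo)))
    hyper.biases[-1][:] = pack_weights(layers, spec)


@dataclass
class HNetModel:
    """A fitted hypernetwork dose-response model."""

    encoder: DenseMLP
    hyper: DenseMLP
    target_spec: TargetNetSpec
    scaler: Scaler
    config: TrainConfig
    seed: int
    history: dict = field(default_factory=dict)

    # -- bookkeeping ---------------------------------------------------
    @property
    def p(self) -> int:
        """Covariate dimensionality expected at prediction time."""
        return self.scaler.p_in

    @property
    def tau(self) -> int:
        return self.target_spec.input_dim

    @property
    def n_params(self) -> int:
        """Trainable parameter count (encoder phi + hypernetwork psi)."""
        return self.encoder.n_params + self.hyper.n_params

    @property
    def _core(self) -> _HNetCore:
        return _HNetCore(self.encoder, self.hyper, self.target_spec)

    # -- prediction ----------------------------------------------------
    def generate_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-instance generated target-net weights, shape (n, m)."""
        Xs = self.scaler.transform_x(np.atleast_2d(X))
        return self._core.omega(Xs)

    def forward_batch(self, X: np.ndarray, T: np.ndarray) -> np.ndarray:
        """Predicted outcomes (original units) for paired rows of X and T."""
        Xs = self.scaler.transform_x(np.atleast_2d(X))
        Ts = self.scaler.transform_t(T)
        if Xs.shape[0] != Ts.shape[0]:
            raise ShapeError(f"X has {Xs.shape[0]} rows but T has {Ts.shape[0]}")
        return self.scaler.inverse_y(self._core.forward(Xs, Ts))

    def _check_support(self, points: np.ndarray) -> None:
        rng_ = self.scaler.t_max[0] - self.scaler.t_min[0]
        lo = self.scaler.t_min[0] - _SUPPORT_SLACK * rng_
        hi = self.scaler.t_max[0] + _SUPPORT_SLACK * rng_
        if points.min() < lo or points.max() > hi:
            warnings.warn(
                f"dose grid [{points.min():.3g}, {points.max():.3g}] extends beyond "
                f"the fitted treatment support [{self.scaler.t_min[0]:.3g}, "
                f"{self.scaler.t_max[0]:.3g}]; curve values are extrapolations",
                ExtrapolationWarning,
                stacklevel=3,
            )

    def predict_curve(self, x: np.ndarray, grid: DoseGrid) -> np.ndarray:
        """Counterfactual dose-response curve for one covariate row.

        The generated weight vector is computed once for ``x`` and reused
        across all grid points.
        """
        return self.predict_curves(np.atleast_2d(x), grid)[0]

    def predict_curves(self, X: np.ndarray, grid: DoseGrid) -> np.ndarray:
        """Stacked counterfactual curves, shape (n, G)."""
        self._check_support(grid.points)
        omega = self.generate_weights(X)
        ts = self.scaler.transform_t(grid.points[:, None])[:, 0]
        return self.scaler.inverse_y(_target_curves(omega, ts, self.target_spec))

    def contrast(self, x: np.ndarray, t_a: float, t_b: float) -> float:
        """Conditional effect contrast: prediction at dose a minus dose b."""
        x = np.atleast_2d(x)
        ta = np.full((1, self.tau), t_a, dtype=float)
        tb = np.full((1, self.tau), t_b, dtype=float)
        return float(self.forward_batch(x, ta)[0] - self.forward_batch(x, tb)[0])

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Serialize to a single .npz archive (spec JSON + flat arrays)."""
        meta = {
            "target_spec": {
                "input_dim": self.target_spec.input_dim,
                "hidden_widths": list(self.target_spec.hidden_widths),
                "activation": self.target_spec.activation,
            },
            "encoder_dims": self.encoder.dims,
            "hyper_dims": self.hyper.dims,
            "activation": self.encoder.activation,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
            "seed": self.seed,
            "history": self.history,
            "kind": "hnet",
        }
        arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        sc = self.scaler
        arrays.update(
            scaler_keep=sc.keep, scaler_x_min=sc.x_min, scaler_x_max=sc.x_max,
            scaler_t_min=sc.t_min, scaler_t_max=sc.t_max,
            scaler_y=np.array([sc.y_mean, sc.y_std]),
        )
        for i, arr in enumerate(self.encoder.params()):
            arrays[f"enc_{i}"] = arr
        for i, arr in enumerate(self.hyper.params()):
            arrays[f"hyp_{i}"] = arr
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path) -> "HNetModel":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            if meta.get("kind") != "hnet":
                raise ValueError(f"{path} does not contain an HNet model")
            cfg_d = meta["config"]
            cfg = TrainConfig(**{
                k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg_d.items()
            })
            spec = TargetNetSpec(
                input_dim=meta["target_spec"]["input_dim"],
                hidden_widths=tuple(meta["target_spec"]["hidden_widths"]),
                activation=meta["target_spec"]["activation"],
            )
            rng = np.random.default_rng(0)
            enc = DenseMLP(meta["encoder_dims"], meta["activation"], rng=rng)
            hyp = DenseMLP(meta["hyper_dims"], meta["activation"], rng=rng)
            for i, arr in enumerate(enc.params()):
                np.copyto(arr, z[f"enc_{i}"])
            for i, arr in enumerate(hyp.params()):
                np.copyto(arr, z[f"hyp_{i}"])
            scaler = Scaler(
                keep=z["scaler_keep"].astype(bool),
                x_min=z["scaler_x_min"], x_max=z["scaler_x_max"],
                t_min=z["scaler_t_min"], t_max=z["scaler_t_max"],
                y_mean=float(z["scaler_y"][0]), y_std=float(z["scaler_y"][1]),
            )
        return cls(encoder=enc, hyper=hyp, target_spec=spec, scaler=scaler,
                   config=cfg, seed=meta["seed"], history=meta["history"])


def _overshoot_penalty(curves_scaled: np.ndarray, cap: float = 3.0) -> float:
    """Degeneracy guard for restart selection.

    Counterfactual curves are evaluated in standardized outcome units; any
    excursion beyond ``cap`` standard deviations of the training outcome is
    a sign of off-support explosion (observed data cannot rule it out, so
    validation loss alone does not catch it).  Returns the mean squared
    excess, 0 for healthy fits.
    """
    excess = np.maximum(np.abs(curves_scaled) - cap, 0.0)
    return float(np.mean(excess ** 2))


def fit(train: ObservationalDataset, config: TrainConfig | None = None,
        seed: int = 0) -> HNetModel:
    """Train an HNet model end-to-end by outcome MSE.

    ``config.n_restarts`` independent initializations are trained; the one
    kept minimizes held-out validation loss plus a degeneracy penalty on
    exploding counterfactual curves.  All stochastic choices (weight init,
    validation split, shuffling) derive from ``seed``; identical seed +
    data + config reproduces the parameters bit for bit.
    """
    cfg = config or TrainConfig()
    scaler = Scaler.fit(train.X, train.T, train.Y)
    Xs = scaler.transform_x(train.X)
    Ts = scaler.transform_t(train.T)
    Ys = scaler.transform_y(train.Y)

    spec = TargetNetSpec(input_dim=train.tau, hidden_widths=cfg.target_hidden,
                         activation=cfg.activation)
    best: HNetModel | None = None
    for ss in np.random.SeedSequence(seed).spawn(max(cfg.n_restarts, 1)):
        ss_init, ss_train = ss.spawn(2)
        rng = np.random.default_rng(ss_init)
        encoder = DenseMLP([Xs.shape[1], *cfg.encoder_widths, cfg.representation_dim],
                           cfg.activation, rng=rng)
        hyper = DenseMLP([cfg.representation_dim, *cfg.hyper_widths, spec.param_count],
                         cfg.activation, rng=rng)
        _stabilize_hyper_output(hyper, spec, cfg.hyper_output_scale, rng)

        core = _HNetCore(encoder, hyper, spec)
        history = train_core(core, Xs, Ts, Ys, cfg, ss_train)
        if spec.input_dim == 1:
            curves = _target_curves(core.omega(Xs[:128]),
                                    np.linspace(0.0, 1.0, 33), spec)
            penalty = _overshoot_penalty(curves)
        else:
            penalty = 0.0
        history["selection_loss"] = history["best_monitor_loss"] + penalty
        model = HNetModel(encoder=encoder, hyper=hyper, target_spec=spec,
                          scaler=scaler, config=cfg, seed=seed, history=history)
        if best is None or (history["selection_loss"]
                            < best.history["selection_loss"]):
            best = model
    return best


def forward_batch(model: HNetModel, X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`HNetModel.forward_batch`."""
    return model.forward_batch(X, T)


def mse_loss(model, batch: tuple[np.ndarray, np.ndarray, np.ndarray]) -> float:
    """Mean squared error of a model on an (X, T, Y) batch, outcome units."""
    X, T, Y = batch
    Y = np.asarray(Y, dtype=float).ravel()
    if Y.size == 0:
        raise ValueError("mse_loss needs a non-empty batch")
    pred = model.forward_batch(X, T)
    return float(np.mean((Y - pred) ** 2))
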