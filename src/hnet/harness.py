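"""Replicate benchmark harness.

Runs the fully synthetic benchmark protocol: draw R independent DGP
instances, fit each model on every instance's training split with
instance-matched but model-isolated seeds, compute MISE/AMSE on the test
split, and aggregate mean ± standard error across replicates.  Per-replicate
records are first-class; the aggregate table is always recomputable from
them.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._training import TrainConfig
from .baselines import fit_slearner
from .data_model import DoseGrid, ObservationalDataset
from .exceptions import ConfigurationError, TrainingError
from .hypernet import fit as fit_hnet
from .metrics import aggregate_replicates, evaluate
from .synthetic_data import DGPSpec, generate_nie2021, replicate_stream

__all__ = ["BenchmarkResult", "run_benchmark", "render_table",
           "MODEL_REGISTRY", "plot_curve_overlay"]

#: model key -> (display name, fit function)
MODEL_REGISTRY: dict[str, tuple[str, Callable]] = {
    "hnet": ("HNet", fit_hnet),
    "slearn_nn": ("SLearn NN", fit_slearner),
}


@dataclass
class BenchmarkResult:
    """Per-replicate metric records plus the configuration that produced them."""

    records: pd.DataFrame  # model, replicate, seed, status, mise, amse, seconds
    config: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean ± SE of MISE/AMSE per model over successful replicates."""
        rows = []
        for key in self.records["model"].unique():
            ok = self.records[(self.records["model"] == key)
                              & (self.records["status"] == "ok")]
            n_failed = int((self.records["model"] == key).sum() - len(ok))
            mise_m, mise_se = aggregate_replicates(ok["mise"])
            amse_m, amse_se = aggregate_replicates(ok["amse"])
            rows.append({
                "model": key,
                "display": MODEL_REGISTRY.get(key, (key, None))[0],
                "mise_mean": mise_m, "mise_se": mise_se,
                "amse_mean": amse_m, "amse_se": amse_se,
                "n_ok": len(ok), "n_failed": n_failed,
            })
        return pd.DataFrame(rows).set_index("model")


def _model_seed(base_seed: int, replicate: int, model_index: int) -> int:
    # separate derived streams: one model's RNG use never perturbs another's
    ss = np.random.SeedSequence([int(base_seed), 7919, replicate, model_index])
    return int(ss.generate_state(1)[0] % 2**31)


def _generate(spec: DGPSpec) -> tuple[ObservationalDataset, ObservationalDataset]:
    if spec.name == "nie2021":
        train, test, _ = generate_nie2021(spec)
        return train, test
    raise ConfigurationError(
        f"unknown DGP {spec.name!r}; available: 'nie2021' "
        "(semi-synthetic benchmarks need externally supplied covariates)"
    )


def run_benchmark(dgp: DGPSpec | None = None,
                  models: tuple[str, ...] = ("hnet", "slearn_nn"),
                  R: int = 20, base_seed: int = 0,
                  grid: DoseGrid | None = None,
                  train_config: TrainConfig | None = None,
                  out_dir=None, verbose: bool = False) -> BenchmarkResult:
    """Fit and evaluate each model on R independent DGP instances.

    A replicate whose training diverges is recorded with status 'failed' and
    excluded from aggregation (never imputed).  With ``out_dir`` set, the
    per-replicate CSV is flushed after every replicate, before any
    aggregation, together with the aggregate JSON, a Markdown table and a
    config snapshot at the end.
    """
    if R < 2:
        raise ValueError("R must be >= 2 to aggregate replicates")
    if not models:
        raise ValueError("models must be non-empty")
    for key in models:
        if key not in MODEL_REGISTRY:
            raise ConfigurationError(
                f"unknown model {key!r}; available: {sorted(MODEL_REGISTRY)}")
    dgp = dgp or DGPSpec()
    grid = grid or DoseGrid.uniform()
    cfg = train_config or TrainConfig()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    config_snapshot = {
        "dgp": vars(dgp).copy(),
        "models": list(models),
        "R": R,
        "base_seed": int(base_seed),
        "grid_size": grid.size,
        "grid_lo": float(grid.points[0]),
        "grid_hi": float(grid.points[-1]),
        "train_config": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in vars(cfg).items()},
    }

    rows: list[dict] = []
    for r, spec_r in enumerate(replicate_stream(base_seed, R, dgp)):
        train, test = _generate(spec_r)
        for mi, key in enumerate(models):
            _, fit_fn = MODEL_REGISTRY[key]
            seed = _model_seed(base_seed, r, mi)
            t0 = time.perf_counter()
            try:
                model = fit_fn(train, cfg, seed=seed)
                rep = evaluate(model, test, grid, model=key)
                rows.append({
                    "model": key, "replicate": r, "seed": seed, "status": "ok",
                    "mise": rep.mise, "amse": rep.amse,
                    "seconds": time.perf_counter() - t0,
                })
            except TrainingError as err:
                rows.append({
                    "model": key, "replicate": r, "seed": seed,
                    "status": f"failed: {err}", "mise": np.nan, "amse": np.nan,
                    "seconds": time.perf_counter() - t0,
                })
            if verbose:
                rec = rows[-1]
                print(f"replicate {r:3d} {key:10s} status={rec['status']} "
                      f"mise={rec['mise']:.4f} amse={rec['amse']:.4f} "
                      f"({rec['seconds']:.1f}s)")
        if out_path is not None:
            pd.DataFrame(rows).to_csv(out_path / "replicates.csv", index=False)

    records = pd.DataFrame(rows)
    # normalize failure status labels for grouping
    records["status"] = np.where(records["status"] == "ok", "ok", "failed")
    result = BenchmarkResult(records=records, config=config_snapshot)

    if out_path is not None:
        agg = result.aggregate().reset_index()
        (out_path / "aggregate.json").write_text(
            json.dumps(agg.to_dict(orient="records"), indent=2))
        (out_path / "table.md").write_text(render_table(result))
        try:
            import yaml
            (out_path / "config.yaml").write_text(yaml.safe_dump(config_snapshot))
        except ImportError:
            (out_path / "config.json").write_text(json.dumps(config_snapshot, indent=2))
    return result


def format_cell(mean: float, se: float) -> str:
    """'mean ± se' at 3 decimals (round-half-even, as in float formatting)."""
    return f"{mean:.3f} ± {se:.3f}"


def render_table(result: BenchmarkResult) -> str:
    """Markdown table: model × {MISE, AMSE} as 'mean ± se'."""
    agg = result.aggregate()
    lines = ["| Model | MISE | AMSE |", "| --- | --- | --- |"]
    for _, row in agg.iterrows():
        lines.append(
            f"| {row['display']} | {format_cell(row['mise_mean'], row['mise_se'])} "
            f"| {format_cell(row['amse_mean'], row['amse_se'])} |"
        )
    n_failed = int(agg["n_failed"].sum())
    if n_failed:
        lines.append(f"\n{n_failed} failed replicate(s) excluded.")
    return "\n".join(lines) + "\n"


def plot_curve_overlay(models: dict, test: ObservationalDataset,
                       grid: DoseGrid | None = None, rows=(0,), path=None):
    """Convenience overlay of predicted vs. true dose-response curves.

    ``models`` maps labels to fitted models; one panel per requested test
    row.  Returns the matplotlib figure (saved to ``path`` if given).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = grid or DoseGrid.uniform()
    rows = list(rows)
    fig, axes = plt.subplots(1, len(rows), figsize=(4 * len(rows), 3.2),
                             squeeze=False)
    for ax, i in zip(axes[0], rows):
        x = test.X[i]
        if test.truth is not None:
            ax.plot(grid.points, test.truth.curve(x, grid), "k--", label="truth")
        for label, model in models.items():
            ax.plot(grid.points, model.predict_curve(x, grid), label=label)
        ax.set_xlabel("treatment t")
        ax.set_ylabel("outcome")
        ax.set_title(f"test unit {i}")
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
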