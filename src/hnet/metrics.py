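"""Dose-response evaluation metrics.

MISE (mean integrated squared error) averages, over test units, the squared
distance between each predicted counterfactual curve and the ground-truth
curve, integrated over the treatment support.  AMSE integrates the squared
distance between the *average* predicted curve and the average true curve —
the error of the estimated average dose-response function.  Both integrals
are approximated by the trapezoid rule on a dose grid; the oracle is
evaluated noiselessly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DoseGrid, ObservationalDataset
from .exceptions import EvaluationError

__all__ = ["MetricReport", "mise", "amse", "evaluate", "aggregate_replicates"]


@dataclass(frozen=True)
class MetricReport:
    """MISE/AMSE for one model on one test set."""

    mise: float
    amse: float
    grid_size: int
    n_test: int
    model: str = ""


def _predicted_curves(predict, X: np.ndarray, grid: DoseGrid) -> np.ndarray:
    """Stack predicted curves (n, G) from a model object or a callable.

    Objects exposing ``predict_curves``/``predict_curve`` are used directly
    (one weight generation per row); a bare callable is treated as a
    per-row ``(x, grid) -> curve`` function.
    """
    if hasattr(predict, "predict_curves"):
        C = np.asarray(predict.predict_curves(X, grid), dtype=float)
    elif hasattr(predict, "predict_curve"):
        C = np.stack([np.asarray(predict.predict_curve(x, grid), dtype=float)
                      for x in X])
    else:
        C = np.stack([np.asarray(predict(x, grid), dtype=float) for x in X])
    if C.shape != (X.shape[0], grid.size):
        raise EvaluationError(
            f"predictor returned shape {C.shape}, expected {(X.shape[0], grid.size)}"
        )
    return C


def _true_curves(test: ObservationalDataset, grid: DoseGrid) -> np.ndarray:
    if test.truth is None:
        raise EvaluationError(
            "test dataset carries no ground-truth oracle; MISE/AMSE need one"
        )
    return test.truth.curves(test.X, grid)


def mise(predict, test: ObservationalDataset,
         grid: DoseGrid | None = None) -> float:
    """Mean over test rows of the integrated squared curve error."""
    grid = grid or DoseGrid.uniform()
    C = _predicted_curves(predict, test.X, grid)
    theta = _true_curves(test, grid)
    per_row = np.trapezoid((C - theta) ** 2, x=grid.points, axis=1)
    return float(per_row.mean())


def amse(predict, test: ObservationalDataset,
         grid: DoseGrid | None = None) -> float:
    """Integrated squared error of the average dose-response curve."""
    grid = grid or DoseGrid.uniform()
    C = _predicted_curves(predict, test.X, grid)
    theta = _true_curves(test, grid)
    diff = C.mean(axis=0) - theta.mean(axis=0)
    return float(np.trapezoid(diff ** 2, x=grid.points))


def evaluate(predict, test: ObservationalDataset,
             grid: DoseGrid | None = None, model: str = "") -> MetricReport:
    """Compute MISE and AMSE with a single pass over the curves."""
    grid = grid or DoseGrid.uniform()
    C = _predicted_curves(predict, test.X, grid)
    theta = _true_curves(test, grid)
    per_row = np.trapezoid((C - theta) ** 2, x=grid.points, axis=1)
    diff = C.mean(axis=0) - theta.mean(axis=0)
    return MetricReport(
        mise=float(per_row.mean()),
        amse=float(np.trapezoid(diff ** 2, x=grid.points)),
        grid_size=grid.size,
        n_test=test.n,
        model=model,
    )


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and standard error of the mean across benchmark replicates."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicate values to aggregate")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
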