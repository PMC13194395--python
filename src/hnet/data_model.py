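"""Datasets, ground-truth dose-response oracles and tabular I/O.

The central container is :class:`ObservationalDataset`, the (Y, T, X) triple
of an observational study with a continuous (possibly vector-valued)
treatment.  Synthetic datasets may carry a :class:`DoseResponseOracle`, the
noiseless outcome surface used by the evaluation metrics.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = [
    "ObservationalDataset",
    "DoseResponseOracle",
    "DoseGrid",
    "load_dataset",
    "save_dataset",
    "train_test_split",
]


@dataclass(frozen=True)
class DoseResponseOracle:
    """A deterministic noiseless outcome surface ``mu(t, x)``.

    ``fn`` must accept ``(t, x)`` where ``t`` is a scalar or an array of
    treatment values and ``x`` a single covariate row, and broadcast over
    ``t``.  Repeated evaluation at identical inputs returns identical values.
    """

    fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    name: str = "oracle"

    def __call__(self, t, x) -> np.ndarray:
        return np.asarray(self.fn(np.asarray(t, dtype=float),
                                  np.asarray(x, dtype=float)), dtype=float)

    def curve(self, x: np.ndarray, grid: "DoseGrid") -> np.ndarray:
        """Noiseless dose-response curve for one covariate row on a grid."""
        return self(grid.points, x)

    def curves(self, X: np.ndarray, grid: "DoseGrid") -> np.ndarray:
        """Stacked curves, shape (n, G), for a covariate matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([self.curve(x, grid) for x in X])


@dataclass(frozen=True)
class DoseGrid:
    """Ordered treatment evaluation points spanning the treatment support."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).ravel()
        if pts.size < 2:
            raise ValueError("a dose grid needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("dose grid points must be finite")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("dose grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @classmethod
    def uniform(cls, lo: float = 0.0, hi: float = 1.0, n: int = 65) -> "DoseGrid":
        return cls(np.linspace(lo, hi, n))

    @property
    def size(self) -> int:
        return self.points.size

    def __len__(self) -> int:
        return self.points.size


def _as_2d(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise DataError(f"{name} must be 1- or 2-dimensional, got ndim={a.ndim}")
    return a


@dataclass(frozen=True)
class ObservationalDataset:
    """The observed (Y, T, X) triple, with an optional ground-truth oracle.

    Attributes
    ----------
    X : (N, p) covariate matrix
    T : (N, tau) treatment matrix (tau = 1 for a scalar treatment)
    Y : (N,) outcome vector
    truth : optional noiseless dose-response oracle (synthetic data only)
    """

    X: np.ndarray
    T: np.ndarray
    Y: np.ndarray
    truth: DoseResponseOracle | None = None
    column_names: dict | None = field(default=None, compare=False)

    def __post_init__(self):
        X = _as_2d(self.X, "X")
        T = _as_2d(self.T, "T")
        Y = np.asarray(self.Y, dtype=float).ravel()
        n = X.shape[0]
        if n < 1:
            raise DataError("dataset must contain at least one row")
        if T.shape[0] != n or Y.shape[0] != n:
            raise DataError(
                f"row counts differ: X has {n}, T has {T.shape[0]}, Y has {Y.shape[0]}"
            )
        for name, arr in (("X", X), ("T", T), ("Y", Y)):
            bad = ~np.isfinite(arr)
            if bad.any():
                row = int(np.argwhere(bad)[0][0])
                raise DataError(f"non-finite value in {name} at row {row}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def tau(self) -> int:
        return self.T.shape[1]

    def __len__(self) -> int:
        return self.n

    def take(self, idx: np.ndarray) -> "ObservationalDataset":
        """Row subset (keeps the oracle and column names)."""
        return replace(self, X=self.X[idx], T=self.T[idx], Y=self.Y[idx])

    def to_frame(self) -> pd.DataFrame:
        names = self.column_names or {}
        xcols = names.get("covariates") or [f"x{j + 1}" for j in range(self.p)]
        tcols = names.get("treatment") or (
            ["t"] if self.tau == 1 else [f"t{j + 1}" for j in range(self.tau)]
        )
        ycol = names.get("outcome") or "y"
        df = pd.DataFrame(self.X, columns=xcols)
        for j, c in enumerate(tcols):
            df[c] = self.T[:, j]
        df[ycol] = self.Y
        return df


def _normalize_column_map(column_map: Mapping) -> tuple[list, list, str]:
    try:
        xcols = list(column_map["covariates"])
        tcols = column_map["treatment"]
        ycol = column_map["outcome"]
    except KeyError as e:
        raise ConfigurationError(
            f"column_map must define 'covariates', 'treatment' and 'outcome'; missing {e}"
        ) from None
    if isinstance(tcols, str):
        tcols = [tcols]
    else:
        tcols = list(tcols)
    if not isinstance(ycol, str):
        raise ConfigurationError("column_map['outcome'] must be a single column name")
    return xcols, tcols, ycol


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    # round_trip parser: bit-exact reload of shortest-repr doubles
    return pd.read_csv(path, float_precision="round_trip")


def load_dataset(path, column_map: Mapping) -> ObservationalDataset:
    """Read an observational dataset from CSV or Parquet.

    ``column_map`` declares which columns hold covariates, treatment(s) and
    the outcome, e.g. ``{"covariates": ["x1", "x2"], "treatment": "t",
    "outcome": "y"}``.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    df = _read_table(path)
    xcols, tcols, ycol = _normalize_column_map(column_map)
    missing = [c for c in (*xcols, *tcols, ycol) if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"column(s) {missing} declared in column_map are absent from {path.name}"
        )
    sub = df[[*xcols, *tcols, ycol]].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(f"non-numeric or missing value at row {row} of {path.name}")
    return ObservationalDataset(
        X=sub[xcols].to_numpy(float),
        T=sub[tcols].to_numpy(float),
        Y=sub[ycol].to_numpy(float),
        column_names={"covariates": xcols, "treatment": tcols, "outcome": ycol},
    )


def save_dataset(ds: ObservationalDataset, path, *, sidecar: bool = True) -> None:
    """Write a dataset to CSV or Parquet, plus a JSON sidecar with the
    column map (``<path>.meta.json``) so it can be reloaded unambiguously."""
    path = Path(path)
    df = ds.to_frame()
    if path.suffix.lower() in {".parquet", ".pq"}:
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)  # shortest-repr floats round-trip exactly
    if sidecar:
        names = ds.column_names or {}
        meta = {
            "covariates": names.get("covariates") or [f"x{j + 1}" for j in range(ds.p)],
            "treatment": names.get("treatment") or (
                ["t"] if ds.tau == 1 else [f"t{j + 1}" for j in range(ds.tau)]
            ),
            "outcome": names.get("outcome") or "y",
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def train_test_split(ds: ObservationalDataset, n_test: int, seed: int
                     ) -> tuple[ObservationalDataset, ObservationalDataset]:
    """Random disjoint partition into (train, test) with ``n_test`` test rows.

    The partition is a deterministic function of ``seed``; the union of the
    two parts is exactly the original row set.
    """
    n_test = int(n_test)
    if not 0 < n_test < ds.n:
        raise ValueError(f"n_test must be in (0, {ds.n}), got {n_test}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return ds.take(train_idx), ds.take(test_idx)
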