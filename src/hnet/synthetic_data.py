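"""Synthetic confounded observational data with known dose-response oracles.

The main generator reproduces the fully synthetic continuous-treatment
benchmark introduced by Nie et al. (2021) alongside VCNet, used widely for
comparing dose-response estimators: six independent Uniform(0,1) covariates,
a treatment obtained by squashing a nonlinear confounded score of the
covariates (plus Gaussian noise) through a logistic link, and an outcome
that is a smooth nonlinear function of treatment and covariates plus
Gaussian noise.  A simple affine-in-treatment generator with controllable
confounding is provided for parameter-recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .data_model import DoseResponseOracle, ObservationalDataset
from .exceptions import ConfigurationError

__all__ = [
    "DGPSpec",
    "generate_nie2021",
    "nie2021_oracle",
    "generate_linear_dgp",
    "replicate_stream",
    "load_continuous_ihdp",
    "load_tcga",
]


@dataclass(frozen=True)
class DGPSpec:
    """One instance of a synthetic data-generating process.

    ``treatment_noise_sd`` is the standard deviation of the Gaussian noise
    added to the confounded treatment score *before* the logistic squashing;
    ``outcome_noise_sd`` is the standard deviation of the additive outcome
    noise.  Defaults follow the Nie et al. (2021) benchmark generator
    (treatment-score noise sd 0.25, outcome noise sd 0.5).
    """

    name: str = "nie2021"
    n_train: int = 500
    n_test: int = 200
    treatment_noise_sd: float = 0.25
    outcome_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")
        if self.treatment_noise_sd < 0 or self.outcome_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


# ---------------------------------------------------------------------------
# Nie et al. (2021) benchmark DGP
# ---------------------------------------------------------------------------

def _nie_score(X: np.ndarray) -> np.ndarray:
    """Confounded treatment score; X has six U(0,1) columns x1..x6.

    score = (10 sin(max(x1,x2,x3)) + max(x3,x4,x5)^3) / (1 + (x1+x5)^2)
            + sin(0.5 x3) (1 + exp(x4 - 0.5 x3))
            + x3^2 + 2 sin(x4) + 2 x5 - 6.5
    """
    x1, x2, x3, x4, x5 = (X[:, j] for j in range(5))
    return (
        (10.0 * np.sin(np.maximum.reduce([x1, x2, x3]))
         + np.maximum.reduce([x3, x4, x5]) ** 3) / (1.0 + (x1 + x5) ** 2)
        + np.sin(0.5 * x3) * (1.0 + np.exp(x4 - 0.5 * x3))
        + x3 ** 2 + 2.0 * np.sin(x4) + 2.0 * x5 - 6.5
    )


def _nie_mu(t, x: np.ndarray) -> np.ndarray:
    """Noiseless outcome surface for one covariate row, broadcast over t.

    mu(t, x) = cos(2 pi (t - 0.5)) (t^2 + 4 max(x1,x6)^3 / (1 + 2 x3^2) sin(x4))
    """
    t = np.asarray(t, dtype=float)
    x1, x3, x4, x6 = x[0], x[2], x[3], x[5]
    amp = 4.0 * max(x1, x6) ** 3 / (1.0 + 2.0 * x3 ** 2) * np.sin(x4)
    return np.cos(2.0 * np.pi * (t - 0.5)) * (t ** 2 + amp)


def _nie_mu_rows(t: np.ndarray, X: np.ndarray) -> np.ndarray:
    """mu evaluated at paired (t_i, x_i) rows."""
    x1, x3, x4, x6 = X[:, 0], X[:, 2], X[:, 3], X[:, 5]
    amp = 4.0 * np.maximum(x1, x6) ** 3 / (1.0 + 2.0 * x3 ** 2) * np.sin(x4)
    return np.cos(2.0 * np.pi * (t - 0.5)) * (t ** 2 + amp)


def nie2021_oracle() -> DoseResponseOracle:
    """The noiseless dose-response surface of the Nie et al. benchmark."""
    return DoseResponseOracle(fn=_nie_mu, name="nie2021")


def generate_nie2021(spec: DGPSpec
                     ) -> tuple[ObservationalDataset, ObservationalDataset,
                                DoseResponseOracle]:
    """Draw one benchmark instance: (train, test, oracle).

    Treatments lie strictly inside (0, 1) by construction (logistic range);
    with ``outcome_noise_sd=0`` the observed outcome equals the oracle.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_train + spec.n_test
    X = rng.uniform(size=(n, 6))
    score = _nie_score(X) + rng.normal(0.0, spec.treatment_noise_sd, size=n)
    t = 1.0 / (1.0 + np.exp(-2.0 * score))
    y = _nie_mu_rows(t, X) + rng.normal(0.0, spec.outcome_noise_sd, size=n)

    oracle = nie2021_oracle()
    train = ObservationalDataset(X=X[:spec.n_train], T=t[:spec.n_train],
                                 Y=y[:spec.n_train], truth=oracle)
    test = ObservationalDataset(X=X[spec.n_train:], T=t[spec.n_train:],
                                Y=y[spec.n_train:], truth=oracle)
    return train, test, oracle


# ---------------------------------------------------------------------------
# Affine-in-treatment DGP for recovery tests
# ---------------------------------------------------------------------------

def _as_fn(value) -> Callable[[np.ndarray], np.ndarray]:
    if callable(value):
        return value
    const = float(value)
    return lambda X: np.full(np.atleast_2d(X).shape[0], const)


def generate_linear_dgp(n: int, p: int = 1, slope_fn=2.0, intercept_fn=0.0,
                        confounding_strength: float = 0.0,
                        noise_sd: float = 0.1, seed: int = 0
                        ) -> tuple[ObservationalDataset, DoseResponseOracle]:
    """y = intercept(x) + slope(x) * t + noise, with optional confounding.

    Covariates are U(0,1); the treatment is a logistic squashing of
    ``confounding_strength`` times a standardized linear score of the
    covariates plus standard Gaussian noise, so ``confounding_strength=0``
    gives a randomized design with t independent of x.

    ``slope_fn``/``intercept_fn`` may be constants or callables mapping a
    covariate matrix (n, p) to a vector (n,).
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    slope = _as_fn(slope_fn)
    intercept = _as_fn(intercept_fn)
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, p))
    # standardized linear score of the covariates (mean 0, variance ~1)
    score = (X.mean(axis=1) - 0.5) * np.sqrt(12.0 * p)
    lin = confounding_strength * score + rng.normal(0.0, 1.0, size=n)
    t = 1.0 / (1.0 + np.exp(-lin))
    y = intercept(X) + slope(X) * t + rng.normal(0.0, noise_sd, size=n)

    def _mu(tt, x):
        x2 = np.atleast_2d(x)
        return intercept(x2)[0] + slope(x2)[0] * np.asarray(tt, dtype=float)

    oracle = DoseResponseOracle(fn=_mu, name="linear")
    ds = ObservationalDataset(X=X, T=t, Y=y, truth=oracle)
    return ds, oracle


# ---------------------------------------------------------------------------
# Replicate seeding
# ---------------------------------------------------------------------------

def replicate_stream(base_seed: int, R: int,
                     template: DGPSpec | None = None) -> list[DGPSpec]:
    """R reproducible DGP instances with collision-free derived seeds.

    Instance ``r`` gets a seed derived from ``(base_seed, r)`` via numpy's
    SeedSequence spawn-key mechanism, so any single instance can be
    regenerated in isolation and the stream is independent of enumeration
    order.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    template = template or DGPSpec()
    specs = []
    for r in range(R):
        ss = np.random.SeedSequence([int(base_seed), r])
        specs.append(replace(template, seed=int(ss.generate_state(1)[0] % 2**31)))
    return specs


# ---------------------------------------------------------------------------
# Semi-synthetic adapters (external covariates required)
# ---------------------------------------------------------------------------

def load_continuous_ihdp(covariates_path=None):
    """Adapter hook for the continuous-IHDP semi-synthetic benchmark.

    The IHDP covariates are an external download and are not bundled;
    supply them and build the treatment/response yourself, or use the
    fully synthetic benchmark (:func:`generate_nie2021`) instead.
    """
    raise ConfigurationError(
        "continuous IHDP requires the externally distributed IHDP covariate "
        "files; pass their location and construct the dataset with "
        "load_dataset(). No covariates were provided."
    )


def load_tcga(covariates_path=None, variant: int = 0):
    """Adapter hook for the TCGA semi-synthetic benchmarks (variants 0-2).

    The 4000-dimensional gene-expression covariates are an external
    download and are not bundled.
    """
    raise ConfigurationError(
        "TCGA requires the externally distributed gene-expression covariates; "
        "pass their location and construct the dataset with load_dataset(). "
        "No covariates were provided."
    )
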