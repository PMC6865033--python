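"""Maximum-likelihood fitting of lifespan models, AIC comparison, bootstrap.

Models are optimized on unconstrained log-transformed coordinates
(``log R, log t0, log(n-1)`` for the network model; ``log R, log G`` for
Gompertz; ``log k, log s`` for Weibull) from a small deterministic start
grid plus seed-controlled jittered restarts.  Right-censored observations
are not supported: replicative-lifespan assays follow every cell to death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import (
    GompertzParams,
    NetworkAgingParams,
    WeibullParams,
)

__all__ = [
    "MODELS",
    "N_PARAMS",
    "LifespanDataset",
    "FitResult",
    "ModelComparison",
    "BootstrapSummary",
    "FitError",
    "BootstrapError",
    "log_likelihood",
    "fit_mle",
    "compare_models",
    "bootstrap_fit",
]

MODELS = ("network", "gompertz", "weibull")
N_PARAMS = {"network": 3, "gompertz": 2, "weibull": 2}
_PARAM_NAMES = {
    "network": ("R", "t0", "n"),
    "gompertz": ("R", "G"),
    "weibull": ("shape", "scale"),
}

_HUGE = 1e300


class FitError(RuntimeError):
    """All optimizer restarts failed; ``best`` carries the best point found."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


class BootstrapError(RuntimeError):
    pass


@dataclass(frozen=True)
class LifespanDataset:
    """Per-cell replicative lifespans for one strain.

    Lifespans are positive, finite reals (integer division counts are
    treated as continuous observations).
    """

    strain_id: str
    lifespans: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.lifespans, dtype=float))
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("lifespans must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("lifespans must be finite")
        if np.any(arr <= 0):
            raise ValueError("lifespans must be strictly positive")
        arr.flags.writeable = False
        object.__setattr__(self, "lifespans", arr)

    @property
    def n_obs(self) -> int:
        return int(self.lifespans.size)

    @property
    def mean(self) -> float:
        return float(self.lifespans.mean())


@dataclass(frozen=True)
class FitResult:
    """Point estimate from one maximum-likelihood fit."""

    model: str
    params: Mapping[str, float]
    loglik: float
    aic: float
    converged: bool
    n_restarts: int

    def params_object(self):
        """Rebuild the typed parameter object for the fitted model."""
        if self.model == "network":
            return NetworkAgingParams(**self.params)
        if self.model == "gompertz":
            return GompertzParams(**self.params)
        if self.model == "weibull":
            return WeibullParams(**self.params)
        raise ValueError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class ModelComparison:
    """Per-model fit results; models whose fit failed are absent."""

    results: Mapping[str, FitResult]

    @property
    def ranking(self) -> list[str]:
        """Model names ordered by ascending AIC."""
        return sorted(self.results, key=lambda m: self.results[m].aic)

    def best(self) -> FitResult:
        return self.results[self.ranking[0]]


@dataclass(frozen=True)
class BootstrapSummary:
    """Mean +/- sd of parameters and AIC across converged bootstrap refits."""

    model: str
    B: int
    n_converged: int
    means: Mapping[str, float]
    sds: Mapping[str, float]
    aic_mean: float
    aic_sd: float
    seed: int | None
    point: FitResult


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _lifespans(data) -> np.ndarray:
    if isinstance(data, LifespanDataset):
        return data.lifespans
    arr = np.atleast_1d(np.asarray(data, dtype=float))
    if arr.size == 0 or not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("lifespan data must be non-empty, finite and >= 0")
    return arr


def _param_vector(model: str, params) -> np.ndarray:
    names = _PARAM_NAMES[model]
    if isinstance(params, Mapping):
        return np.array([float(params[k]) for k in names])
    if isinstance(params, (NetworkAgingParams, GompertzParams, WeibullParams)):
        return np.array([float(getattr(params, k)) for k in names])
    arr = np.asarray(params, dtype=float)
    if arr.shape != (len(names),):
        raise ValueError(f"expected {len(names)} parameters for {model!r}")
    return arr


def _loglik_terms(model: str, vec: np.ndarray, t: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        if model == "network":
            R, t0, n = vec
            u = np.log1p(t / t0)
            return np.log(R) + (n - 1.0) * u + (R * t0 / n) * (1.0 - np.exp(n * u))
        if model == "gompertz":
            R, G = vec
            if G > 0:
                return np.log(R) + G * t + (R / G) * -np.expm1(G * t)
            return np.log(R) - R * t
        if model == "weibull":
            k, s = vec
            z = t / s
            return np.log(k) - np.log(s) + (k - 1.0) * np.log(z) - z**k
    raise ValueError(f"unknown model {model!r}")


def log_likelihood(model: str, params, data) -> float:
    """Total log-likelihood ``sum_i ln f(t_i)`` of ``data`` under ``model``.

    Returns ``-inf`` (never raises) when any observation has zero density
    under the given parameters.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    t = _lifespans(data)
    vec = _param_vector(model, params)
    terms = _loglik_terms(model, vec, t)
    total = float(np.sum(terms))
    if np.isnan(total) or total == np.inf:
        return -np.inf
    return total


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def _pack(model: str, vec: np.ndarray) -> np.ndarray:
    if model == "network":
        R, t0, n = vec
        return np.log([R, t0, n - 1.0])
    return np.log(np.asarray(vec, dtype=float))


def _unpack(model: str, theta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        v = np.exp(np.asarray(theta, dtype=float))
    if model == "network":
        return np.array([v[0], v[1], v[2] + 1.0])
    return v


def _default_starts(model: str, t: np.ndarray) -> list[np.ndarray]:
    """Deterministic start grid; R (or sigma) matched to the sample median."""
    tm = float(np.median(t))
    mean = float(np.mean(t))
    starts: list[np.ndarray] = []
    if model == "network":
        for f in (0.5, 1.0, 2.0, 4.0):
            t0 = f * mean
            for n in (2.0, 4.0, 8.0, 16.0):
                # R such that the model median equals the sample median
                R = n * np.log(2.0) / (t0 * np.expm1(n * np.log1p(tm / t0)))
                starts.append(_pack(model, np.array([R, t0, n])))
    elif model == "gompertz":
        for G in (0.01, 0.05, 0.1, 0.3):
            R = G * np.log(2.0) / np.expm1(G * tm)
            starts.append(_pack(model, np.array([R, G])))
    elif model == "weibull":
        for k in (0.5, 1.0, 2.0, 4.0, 8.0):
            s = tm / np.log(2.0) ** (1.0 / k)
            starts.append(_pack(model, np.array([k, s])))
    else:
        raise ValueError(f"unknown model {model!r}")
    return starts


def fit_mle(
    model: str,
    data,
    *,
    restarts: int = 4,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | None = None,
    starts: Sequence[np.ndarray] | None = None,
) -> FitResult:
    """Maximize the log-likelihood of ``model`` over its parameter domain.

    Runs Nelder-Mead from every start in the deterministic grid (or the
    caller-supplied ``starts``) plus ``restarts`` seed-jittered copies of
    the best grid start; the best final log-likelihood wins, ties broken by
    first found.  Deterministic for a fixed seed and options.

    Raises
    ------
    FitError
        If no start yields a finite log-likelihood.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    t = _lifespans(data)
    if t.size < 10:
        warnings.warn(
            f"only {t.size} observations; estimates will be unstable",
            UserWarning,
            stacklevel=2,
        )

    def objective(theta: np.ndarray) -> float:
        vec = _unpack(model, theta)
        ll = log_likelihood(model, vec, t)
        return -ll if np.isfinite(ll) else _HUGE

    start_list = [np.asarray(s, dtype=float) for s in (starts or _default_starts(model, t))]
    if restarts > 0:
        rng = np.random.default_rng(seed)
        base = min(start_list, key=objective)
        start_list = start_list + [
            base + rng.normal(0.0, 0.3, size=base.size) for _ in range(restarts)
        ]

    best = None
    n_runs = 0
    for theta0 in start_list:
        res = minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-7,
                "fatol": tol,
                "maxiter": max_iter,
                "maxfev": 4 * max_iter,
            },
        )
        n_runs += 1
        if best is None or res.fun < best.fun:
            best = res

    assert best is not None
    loglik = -float(best.fun)
    if not np.isfinite(loglik) or best.fun >= _HUGE:
        raise FitError(
            f"no restart reached a finite likelihood for model {model!r}",
            best=None,
        )
    vec = _unpack(model, best.x)
    params = dict(zip(_PARAM_NAMES[model], (float(v) for v in vec)))
    k = N_PARAMS[model]
    return FitResult(
        model=model,
        params=params,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        converged=bool(best.success),
        n_restarts=n_runs,
    )


def compare_models(data, models: Sequence[str] = MODELS, **fit_options) -> ModelComparison:
    """Fit each model to ``data``; non-converging models are omitted."""
    results: dict[str, FitResult] = {}
    for model in models:
        try:
            results[model] = fit_mle(model, data, **fit_options)
        except FitError:
            continue
    if not results:
        raise FitError("every model failed to fit")
    return ModelComparison(results=results)


def bootstrap_fit(
    model: str,
    data,
    B: int = 100,
    seed: int | None = None,
    *,
    indices_fn: Callable[[int], np.ndarray] | None = None,
    **fit_options,
) -> BootstrapSummary:
    """Bootstrap-with-replacement uncertainty for a maximum-likelihood fit.

    Fits the full dataset first (multi-start), then refits ``B`` resamples
    of size ``n_obs`` starting from the point estimate.  Reports per-
    parameter mean and sd over the converged refits; fails if more than half
    of the refits fail.  ``indices_fn`` is a test hook that overrides the
    resampling indices for replicate ``b``.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B!r}")
    t = _lifespans(data)
    rng = np.random.default_rng(seed)
    point = fit_mle(model, t, seed=seed, **fit_options)
    start = _pack(model, _param_vector(model, point.params))

    names = _PARAM_NAMES[model]
    draws: list[FitResult] = []
    for b in range(B):
        idx = indices_fn(b) if indices_fn is not None else rng.integers(0, t.size, t.size)
        try:
            fr = fit_mle(model, t[idx], starts=[start], restarts=0, **fit_options)
        except (FitError, ValueError):
            continue
        draws.append(fr)

    if len(draws) * 2 < B:
        raise BootstrapError(
            f"{B - len(draws)}/{B} bootstrap refits failed for model {model!r} "
            f"on strain data of size {t.size}"
        )
    mat = np.array([[fr.params[k] for k in names] for fr in draws])
    aics = np.array([fr.aic for fr in draws])
    ddof = 1 if len(draws) > 1 else 0
    return BootstrapSummary(
        model=model,
        B=B,
        n_converged=len(draws),
        means=dict(zip(names, np.mean(mat, axis=0).tolist())),
        sds=dict(zip(names, np.std(mat, axis=0, ddof=ddof).tolist())),
        aic_mean=float(np.mean(aics)),
        aic_sd=float(np.std(aics, ddof=ddof)),
        seed=seed,
        point=point,
    )
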