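"""Synthetic lifespan generation and empirical hazard diagnostics.

Two routes are provided: exact inverse-CDF sampling from the closed-form
network survival function, and a mechanistic simulation of the network
itself (binomially wired modules whose interactions decay exponentially).
The two agree at early ages, which is how the Gompertz-like rise of
mortality emerges from purely non-aging parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import MechanisticNetworkSpec, NetworkAgingParams
from .fitting import LifespanDataset

__all__ = [
    "HazardCurve",
    "EarlyGompertz",
    "closed_form_quantile",
    "sample_closed_form",
    "simulate_mechanistic",
    "empirical_hazard",
    "early_gompertz_estimate",
]


@dataclass(frozen=True)
class HazardCurve:
    """Binned empirical hazard: deaths / (at-risk x bin width) per bin."""

    midpoints: np.ndarray
    hazard: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        if np.any(self.hazard < 0):
            raise ValueError("hazards must be non-negative")
        if np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at-risk counts must be non-increasing")

    def standard_error(self) -> np.ndarray:
        """Poisson-count Monte-Carlo standard error per bin.

        Uses ``sqrt(deaths + 1)`` so zero-death bins keep a usable
        (conservative) error scale.
        """
        return np.sqrt(self.deaths + 1.0) / (self.at_risk * self.bin_width)


class EarlyGompertz(NamedTuple):
    """Gompertz parameters read off an early-age log-hazard regression."""

    R: float
    G: float


def closed_form_quantile(params: NetworkAgingParams, survival) -> float | np.ndarray:
    """Age at which network survival equals ``survival`` (inverse CDF).

    ``t = t0 * ((1 - n*ln(u) / (R*t0))**(1/n) - 1)`` for ``u`` in (0, 1];
    ``u = 1`` maps to 0 and ``u -> 0`` diverges.
    """
    u = np.asarray(survival, dtype=float)
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("survival values must lie in (0, 1]")
    inner = 1.0 - params.n * np.log(u) / (params.R * params.t0)
    t = params.t0 * np.expm1(np.log(inner) / params.n)
    return float(t) if np.ndim(survival) == 0 else t


def sample_closed_form(
    params: NetworkAgingParams,
    n_samples: int,
    seed: int | None = None,
    strain_id: str = "closed_form",
) -> LifespanDataset:
    """Draw ``n_samples`` lifespans by exact inversion of the network survival."""
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples!r}")
    rng = np.random.default_rng(seed)
    u = 1.0 - rng.uniform(size=n_samples)  # in (0, 1]
    return LifespanDataset(strain_id, closed_form_quantile(params, u))


def simulate_mechanistic(
    spec: MechanisticNetworkSpec,
    n_cells: int,
    seed: int | None = None,
    strain_id: str = "mechanistic",
    _chunk: int = 4096,
) -> LifespanDataset:
    """Simulate cell lifespans from the mechanistic network.

    Per cell: each of the ``m`` modules draws its number of initially
    active interactions from a binomial(n, p) conditioned on >= 1 (cells
    are born with every essential module functional); the module fails when
    the last of those interactions decays (max of k iid exponential(lam)
    times, drawn by inverting the max-order-statistic CDF); the cell dies
    at the first module failure.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells!r}")
    rng = np.random.default_rng(seed)
    out = np.empty(n_cells, dtype=float)
    pos = 0
    while pos < n_cells:
        size = min(_chunk, n_cells - pos)
        k = rng.binomial(spec.n, spec.p, size=(size, spec.m))
        empty = k == 0
        while empty.any():  # rejection step implements the k >= 1 conditioning
            k[empty] = rng.binomial(spec.n, spec.p, size=int(empty.sum()))
            empty = k == 0
        u = rng.uniform(size=(size, spec.m))
        with np.errstate(divide="ignore"):
            # max of k exponentials: T = -ln(1 - u**(1/k)) / lam
            module_t = -np.log(-np.expm1(np.log(u) / k)) / spec.lam
        out[pos : pos + size] = module_t.min(axis=1)
        pos += size
    # guard the measure-zero u == 0 draw, which would give a zero lifespan
    out[out <= 0] = np.finfo(float).tiny
    return LifespanDataset(strain_id, out)


def empirical_hazard(data: LifespanDataset, bin_width: float = 1.0) -> HazardCurve:
    """Discrete hazard estimate: deaths / (at-risk x width) on a uniform grid.

    Bins start at age 0; trailing bins with nobody at risk are dropped.
    """
    if not bin_width > 0:
        raise ValueError(f"bin width must be positive, got {bin_width!r}")
    t = data.lifespans
    if t.size < 100:
        warnings.warn(
            f"only {t.size} observations; hazard estimates will be noisy",
            UserWarning,
            stacklevel=2,
        )
    n_bins = max(int(np.ceil(t.max() / bin_width)), 1)
    edges = bin_width * np.arange(n_bins + 1)
    deaths, _ = np.histogram(t, bins=edges)  # last bin is closed on the right
    at_risk = t.size - np.concatenate([[0], np.cumsum(deaths)[:-1]])
    keep = at_risk > 0
    mid = 0.5 * (edges[:-1] + edges[1:])
    return HazardCurve(
        midpoints=mid[keep],
        hazard=deaths[keep] / (at_risk[keep] * bin_width),
        at_risk=at_risk[keep].astype(float),
        deaths=deaths[keep].astype(float),
        bin_width=float(bin_width),
    )


def early_gompertz_estimate(curve: HazardCurve, t_max: float) -> EarlyGompertz:
    """Fit ``ln hazard = ln R + G*t`` over bins with midpoint <= ``t_max``.

    Weighted least squares with death counts as weights; zero-hazard bins
    are excluded.  This is the diagnostic used to read the emergent
    Gompertz coefficient off a mechanistic simulation.
    """
    sel = (curve.midpoints <= t_max) & (curve.hazard > 0)
    if int(sel.sum()) < 3:
        raise ValueError("need at least 3 positive-hazard bins below t_max")
    x = curve.midpoints[sel]
    y = np.log(curve.hazard[sel])
    w = np.sqrt(curve.deaths[sel])
    slope, intercept = np.polyfit(x, y, 1, w=w)
    return EarlyGompertz(R=float(np.exp(intercept)), G=float(slope))
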