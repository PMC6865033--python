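"""Closed-form building blocks of the binomial gene-network aging model.

The model composes ``m`` essential modules in series.  Each module is one
essential node together with ``n`` redundant interactions whose strengths
decay exponentially (rate ``lam``) — non-aging parts.  A module fails when
all of its interactions have decayed; the cell dies when any module fails.
Binomial wiring at birth (each interaction active with probability ``p``)
yields the three-parameter hazard ``R * (1 + t/t0)**(n - 1)``, which is
Gompertz-like for ``t << t0``.

All hazard/survival/density functions accept scalar or array ages and
return a matching scalar or :class:`numpy.ndarray`.  Time is measured in
cell divisions throughout, but continuous ages are accepted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import comb

__all__ = [
    "NetworkAgingParams",
    "MechanisticNetworkSpec",
    "GompertzParams",
    "WeibullParams",
    "HazardSurvivalDensity",
    "DecayRate",
    "module_survival",
    "module_hazard",
    "module_hazard_early",
    "network_hazard_binomial",
    "network_hazard",
    "network_survival",
    "network_density",
    "gompertz_model",
    "weibull_model",
    "gompertz_coefficient",
    "phenomenological_from_mechanistic",
    "decay_rate_from_t0",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkAgingParams:
    """Phenomenological network-aging parameters ``(R, t0, n)``.

    Parameters
    ----------
    R : float
        Initial mortality rate (per cell division) at age zero.
    t0 : float
        Initial virtual age of the system (cell divisions).
    n : float
        Apparent average number of lifespan-influencing interactions per
        essential node.  Real-valued; ``n == 1`` degenerates to a constant
        hazard and is rejected.
    """

    R: float
    t0: float
    n: float

    def __post_init__(self) -> None:
        for name in ("R", "t0", "n"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.R <= 0:
            raise ValueError(f"R must be > 0, got {self.R!r}")
        if self.t0 <= 0:
            raise ValueError(f"t0 must be > 0, got {self.t0!r}")
        if self.n <= 1:
            raise ValueError(
                f"n must be > 1 (n == 1 is a constant hazard), got {self.n!r}"
            )


@dataclass(frozen=True)
class MechanisticNetworkSpec:
    """Mechanistic network description ``(m, n, p, lam)``.

    ``m`` essential modules, each with integer ``n`` interaction slots;
    an interaction is active at birth with probability ``p`` and decays at
    rate ``lam``.  The derived constant ``c = 1/(1 - (1-p)**n)`` normalizes
    for modules conditioned to be born with at least one active interaction.
    """

    m: int
    n: int
    p: float
    lam: float

    def __post_init__(self) -> None:
        if not float(self.m).is_integer() or self.m < 1:
            raise ValueError(f"m must be an integer >= 1, got {self.m!r}")
        if not float(self.n).is_integer() or self.n < 1:
            raise ValueError(f"n must be an integer >= 1, got {self.n!r}")
        object.__setattr__(self, "m", int(self.m))
        object.__setattr__(self, "n", int(self.n))
        if not 0 < self.p <= 1:
            raise ValueError(f"p must be in (0, 1], got {self.p!r}")
        if not (math.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"lam must be finite and > 0, got {self.lam!r}")

    @property
    def c(self) -> float:
        """Normalizing constant ``1/(1 - (1-p)**n)`` (>= 1; == 1 iff p == 1)."""
        return 1.0 / -math.expm1(self.n * math.log1p(-self.p)) if self.p < 1 else 1.0


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard parameters: ``mu(t) = R * exp(G*t)``.

    ``G == 0`` is the non-aging exponential-decay limit.
    """

    R: float
    G: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.R) and self.R > 0):
            raise ValueError(f"R must be finite and > 0, got {self.R!r}")
        if not (math.isfinite(self.G) and self.G >= 0):
            raise ValueError(f"G must be finite and >= 0, got {self.G!r}")


@dataclass(frozen=True)
class WeibullParams:
    """Weibull shape/scale parameters with hazard ``(k/s)*(t/s)**(k-1)``."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be finite and > 0, got {self.shape!r}")
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be finite and > 0, got {self.scale!r}")


class HazardSurvivalDensity(NamedTuple):
    hazard: float | np.ndarray
    survival: float | np.ndarray
    density: float | np.ndarray


class DecayRate(NamedTuple):
    """Interaction decay rate ``lam`` and its characteristic time ``1/lam``."""

    lam: float
    tau: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _validate_time(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("age t must be finite and non-negative")
    return arr


def _match(value: np.ndarray, t) -> float | np.ndarray:
    if np.ndim(t) == 0:
        return float(value)
    return value


# ---------------------------------------------------------------------------
# essential-module functions
# ---------------------------------------------------------------------------


def module_survival(lam: float, n: int, t) -> float | np.ndarray:
    """Viability of one essential module, ``1 - (1 - exp(-lam*t))**n``.

    The module holds ``n`` parallel non-aging interactions, each with
    constant decay rate ``lam``; it survives while at least one is intact.
    """
    if not lam > 0:
        raise ValueError(f"lam must be > 0, got {lam!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    tt = _validate_time(t)
    q = -np.expm1(-lam * tt)  # 1 - exp(-lam t), in [0, 1)
    with np.errstate(divide="ignore"):
        s = np.where(q > 0.0, -np.expm1(n * np.log(np.where(q > 0.0, q, 1.0))), 1.0)
    return _match(s, t)


def module_hazard(lam: float, n: int, t) -> float | np.ndarray:
    """Mortality rate of one essential module.

    ``n*lam*exp(-lam*t)*(1-exp(-lam*t))**(n-1) / (1 - (1-exp(-lam*t))**n)``;
    zero at ``t = 0`` for ``n > 1`` and constant ``lam`` for ``n == 1``.

    Raises
    ------
    OverflowError
        If the module survival underflows to zero at some requested age,
        where the hazard is no longer representable.
    """
    if not lam > 0:
        raise ValueError(f"lam must be > 0, got {lam!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    tt = _validate_time(t)
    q = -np.expm1(-lam * tt)
    s = np.asarray(module_survival(lam, n, tt))
    if np.any(s <= 0.0):
        bad = tt[np.asarray(s) <= 0.0] if np.ndim(tt) else tt
        raise OverflowError(
            f"module survival underflowed to 0 (lam={lam}, n={n}, t={bad}); "
            "hazard is not representable there"
        )
    mu = n * lam * np.exp(-lam * tt) * q ** (n - 1) / s
    return _match(mu, t)


def module_hazard_early(lam: float, n: int, t) -> float | np.ndarray:
    """Early-age module hazard ``n * lam**n * t**(n-1)``, valid for ``t << 1/lam``."""
    if not lam > 0:
        raise ValueError(f"lam must be > 0, got {lam!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    tt = _validate_time(t)
    mu = n * lam**n * tt ** (n - 1)
    return _match(mu, t)


# ---------------------------------------------------------------------------
# network functions
# ---------------------------------------------------------------------------


def network_hazard_binomial(spec: MechanisticNetworkSpec, t) -> float | np.ndarray:
    """Network mortality rate as the explicit binomial sum over wiring patterns.

    ``c*m*n*lam*p * sum_{i=1..n} C(n-1, i-1) (p*lam*t)**(i-1) (1-p)**(n-i)``.

    Valid for ``t << 1/lam``; a :class:`RuntimeWarning` is emitted when any
    requested age exceeds ``1/lam``.  Kept as an explicit summation so it can
    be cross-checked against the closed form :func:`network_hazard`.
    """
    tt = _validate_time(t)
    if np.any(tt * spec.lam > 1.0):
        warnings.warn(
            "network_hazard_binomial is an early-age approximation; "
            "requested ages exceed 1/lam",
            RuntimeWarning,
            stacklevel=2,
        )
    n, p, lam = spec.n, spec.p, spec.lam
    i = np.arange(1, n + 1)
    coeff = comb(n - 1, i - 1) * (1.0 - p) ** (n - i)
    x = p * lam * tt
    powers = np.power.outer(np.asarray(x), i - 1)  # x**0 at x=0 -> 1
    total = powers @ coeff
    mu = spec.c * spec.m * n * lam * p * total
    return _match(mu, t)


def network_hazard(params: NetworkAgingParams, t) -> float | np.ndarray:
    """Closed-form network mortality rate ``R * (1 + t/t0)**(n-1)``."""
    tt = _validate_time(t)
    with np.errstate(over="ignore"):
        mu = params.R * np.exp((params.n - 1.0) * np.log1p(tt / params.t0))
    return _match(mu, t)


def _log_network_survival(params: NetworkAgingParams, tt: np.ndarray) -> np.ndarray:
    # (R*t0/n) * (1 - (1 + t/t0)**n), evaluated so that overflow of the
    # power term yields -inf (survival 0) instead of a NaN.
    with np.errstate(over="ignore"):
        grow = np.exp(params.n * np.log1p(tt / params.t0))
        return (params.R * params.t0 / params.n) * (1.0 - grow)


def network_survival(params: NetworkAgingParams, t) -> float | np.ndarray:
    """Network survival ``exp((R*t0/n) * (1 - (1 + t/t0)**n))``.

    Monotone decreasing from 1 at ``t = 0``; underflows cleanly to 0 at
    extreme ages.
    """
    tt = _validate_time(t)
    s = np.exp(_log_network_survival(params, tt))
    return _match(s, t)


def network_density(params: NetworkAgingParams, t) -> float | np.ndarray:
    """Lifespan probability density ``f(t) = S(t) * mu(t)`` of the network model."""
    tt = _validate_time(t)
    log_mu = np.log(params.R) + (params.n - 1.0) * np.log1p(tt / params.t0)
    f = np.exp(_log_network_survival(params, tt) + log_mu)
    return _match(f, t)


# ---------------------------------------------------------------------------
# reference models
# ---------------------------------------------------------------------------


def gompertz_model(params: GompertzParams, t) -> HazardSurvivalDensity:
    """Gompertz hazard, survival and density at age(s) ``t``.

    ``mu = R*exp(G*t)``; ``S = exp((R/G)*(1 - exp(G*t)))`` for ``G > 0`` and
    the exponential limit ``exp(-R*t)`` for ``G == 0``.
    """
    tt = _validate_time(t)
    R, G = params.R, params.G
    with np.errstate(over="ignore"):
        hazard = R * np.exp(G * tt)
        if G > 0:
            log_s = (R / G) * -np.expm1(G * tt)
        else:
            log_s = -R * tt
        survival = np.exp(log_s)
        density = np.exp(log_s + np.log(R) + G * tt)
    return HazardSurvivalDensity(
        _match(hazard, t), _match(survival, t), _match(density, t)
    )


def weibull_model(params: WeibullParams, t) -> HazardSurvivalDensity:
    """Weibull hazard, survival and density at age(s) ``t``.

    Shape/scale convention: hazard ``(k/s)*(t/s)**(k-1)``.  At ``t = 0`` with
    ``k < 1`` the hazard (and density) is infinite and returned as ``inf``.
    """
    tt = _validate_time(t)
    k, s = params.shape, params.scale
    z = tt / s
    with np.errstate(divide="ignore", over="ignore"):
        hazard = (k / s) * z ** (k - 1.0)
        survival = np.exp(-(z**k))
        density = hazard * survival
    return HazardSurvivalDensity(
        _match(hazard, t), _match(survival, t), _match(density, t)
    )


def gompertz_coefficient(params: NetworkAgingParams) -> float:
    """Early-age Gompertz coefficient implied by the network model, ``(n-1)/t0``."""
    return (params.n - 1.0) / params.t0


# ---------------------------------------------------------------------------
# mechanistic <-> phenomenological mappings
# ---------------------------------------------------------------------------


def phenomenological_from_mechanistic(
    spec: MechanisticNetworkSpec,
) -> NetworkAgingParams:
    """Map ``(m, n, p, lam)`` to ``(R, t0, n)``.

    ``t0 = (1-p)/(p*lam)`` and ``R = c*m*n*(p*lam)**n * t0**(n-1)``.

    Raises
    ------
    ValueError
        If ``p == 1`` (then ``t0 = 0``, outside the phenomenological domain)
        or ``n == 1`` (constant hazard, rejected by
        :class:`NetworkAgingParams`).
    """
    if spec.p >= 1.0:
        raise ValueError("p = 1 gives t0 = 0; no phenomenological equivalent")
    t0 = (1.0 - spec.p) / (spec.p * spec.lam)
    R = spec.c * spec.m * spec.n * (spec.p * spec.lam) ** spec.n * t0 ** (spec.n - 1)
    return NetworkAgingParams(R=R, t0=t0, n=float(spec.n))


def decay_rate_from_t0(t0: float, p: float) -> DecayRate:
    """Back out the interaction decay rate from ``t0`` under an assumed ``p``.

    ``lam = (1-p)/(p*t0)``; the companion characteristic time ``tau = 1/lam
    = p*t0/(1-p)`` is the quantity usually quoted.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p!r}")
    if not (math.isfinite(t0) and t0 > 0):
        raise ValueError(f"t0 must be finite and > 0, got {t0!r}")
    lam = (1.0 - p) / (p * t0)
    return DecayRate(lam=lam, tau=1.0 / lam)
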