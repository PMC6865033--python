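"""Cross-strain analyses over fitted parameter tables.

Operates on a per-strain table of fitted network parameters (R, t0, n) and
Gompertz parameters (R, G): Strehler-Mildvan correlation, generic column
correlations, a product-of-coefficients mediation test with percentile
bootstrap, interaction-decay back-calculations under an assumed activation
probability, and column summaries.  A 15-strain wild-isolate parameter
table ships with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "StrainParameterTable",
    "CorrelationResult",
    "MediationResult",
    "DecaySummary",
    "ColumnSummary",
    "load_wild_isolates",
    "strehler_mildvan",
    "parameter_correlation",
    "mediation_test",
    "decay_summary",
    "column_summary",
]

REQUIRED_COLUMNS = (
    "strain",
    "avg_rls",
    "network_R",
    "t0",
    "n",
    "gompertz_R",
    "gompertz_G",
)

_FIXTURE = "table2_wild_isolates.tsv"


@dataclass(frozen=True)
class StrainParameterTable:
    """One row of fitted parameters per strain.

    Required columns: strain, avg_rls, network_R, t0, n, gompertz_R,
    gompertz_G; extra columns (sds, AICs) are carried through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if len(df) == 0:
            raise ValueError("table must have at least one strain")
        if df["strain"].duplicated().any():
            dup = df.loc[df["strain"].duplicated(), "strain"].tolist()
            raise ValueError(f"duplicate strain ids: {dup}")
        numeric = [c for c in REQUIRED_COLUMNS if c != "strain"]
        values = df[numeric].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("all parameter entries must be finite and positive")
        if np.any(df["n"].to_numpy(dtype=float) <= 1):
            raise ValueError("network n must be > 1 for every strain")
        object.__setattr__(self, "data", df)

    @classmethod
    def from_tsv(cls, path) -> "StrainParameterTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def strains(self) -> list[str]:
        return self.data["strain"].tolist()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


def load_wild_isolates() -> StrainParameterTable:
    """Load the packaged 15-strain wild-isolate parameter table."""
    with resources.as_file(
        resources.files("netaging").joinpath("data", _FIXTURE)
    ) as path:
        return StrainParameterTable.from_tsv(path)


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    pvalue: float
    n_strains: int
    degenerate: bool = False


@dataclass(frozen=True)
class MediationResult:
    """Linear product-of-coefficients mediation estimate.

    ``total = direct + indirect`` exactly for same-sample OLS fits;
    ``proportion_mediated = indirect / total``.  The confidence interval is
    a percentile bootstrap over strains on the proportion mediated.
    """

    total_effect: float
    direct_effect: float
    indirect_effect: float
    proportion_mediated: float
    ci_low: float
    ci_high: float
    B: int
    seed: int | None
    n_strains: int


class DecaySummary(NamedTuple):
    """Summary of per-strain 1/lam back-calculated under an assumed p."""

    p: float
    mean: int
    minimum: int
    maximum: int


class ColumnStats(NamedTuple):
    mean: float
    minimum: float
    maximum: float


class ColumnSummary(NamedTuple):
    t0: ColumnStats
    n: ColumnStats
    avg_rls: ColumnStats


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _corr(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            slope=math.nan,
            intercept=math.nan,
            r=math.nan,
            r_squared=math.nan,
            pvalue=math.nan,
            n_strains=len(x),
            degenerate=True,
        )
    res = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        pvalue=float(res.pvalue),
        n_strains=len(x),
    )


def strehler_mildvan(
    table: StrainParameterTable, which_R: str = "gompertz"
) -> CorrelationResult:
    """OLS of the Gompertz coefficient G on log10 of the initial mortality rate.

    ``which_R`` selects the ``gompertz_R`` (default, the conventional
    choice) or ``network_R`` column.
    """
    if which_R not in ("gompertz", "network"):
        raise ValueError(f"which_R must be 'gompertz' or 'network', got {which_R!r}")
    if len(table) < 3:
        raise ValueError(f"need at least 3 strains, got {len(table)}")
    x = np.log10(table.column(f"{which_R}_R"))
    y = table.column("gompertz_G")
    return _corr(x, y)


def parameter_correlation(
    table: StrainParameterTable,
    x: str,
    y: str,
    x_transform: Callable[[np.ndarray], np.ndarray] | None = None,
    y_transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> CorrelationResult:
    """OLS/Pearson correlation between two (optionally transformed) columns."""
    if len(table) < 3:
        raise ValueError(f"need at least 3 strains, got {len(table)}")
    xv = table.column(x)
    yv = table.column(y)
    if x_transform is not None:
        xv = np.asarray(x_transform(xv), dtype=float)
    if y_transform is not None:
        yv = np.asarray(y_transform(yv), dtype=float)
    return _corr(xv, yv)


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _product_of_coefficients(
    x: np.ndarray, m: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    ones = np.ones_like(x)
    total = _ols_coef(np.column_stack([ones, x]), y)[1]
    beta = _ols_coef(np.column_stack([ones, x, m]), y)
    direct, b = beta[1], beta[2]
    a = _ols_coef(np.column_stack([ones, x]), m)[1]
    indirect = a * b
    return float(total), float(direct), float(indirect), float(
        indirect / (indirect + direct)
    )


def mediation_test(
    table: StrainParameterTable,
    exposure: str = "gompertz_R",
    mediator: str = "t0",
    outcome: str = "gompertz_G",
    B: int = 1000,
    seed: int | None = None,
    exposure_transform: Callable[[np.ndarray], np.ndarray] | None = np.log10,
) -> MediationResult:
    """Product-of-coefficients mediation with a percentile bootstrap CI.

    Total effect c from outcome ~ exposure; direct effect c' and mediator
    slope b from outcome ~ exposure + mediator; a from mediator ~ exposure;
    indirect effect a*b and proportion mediated a*b / (a*b + c').  The
    exposure is log10-transformed by default.
    """
    if len(table) < 5:
        raise ValueError(f"need at least 5 strains, got {len(table)}")
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B!r}")
    x = table.column(exposure)
    if exposure_transform is not None:
        x = np.asarray(exposure_transform(x), dtype=float)
    m = table.column(mediator)
    y = table.column(outcome)
    if np.ptp(x) == 0 or np.ptp(m) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (zero-variance) column in mediation inputs")

    total, direct, indirect, prop = _product_of_coefficients(x, m, y)

    rng = np.random.default_rng(seed)
    props = np.empty(B)
    size = len(x)
    for b in range(B):
        idx = rng.integers(0, size, size)
        while np.ptp(x[idx]) == 0 or np.ptp(m[idx]) == 0:
            idx = rng.integers(0, size, size)
        props[b] = _product_of_coefficients(x[idx], m[idx], y[idx])[3]
    lo, hi = np.percentile(props, [2.5, 97.5])

    return MediationResult(
        total_effect=total,
        direct_effect=direct,
        indirect_effect=indirect,
        proportion_mediated=prop,
        ci_low=float(lo),
        ci_high=float(hi),
        B=B,
        seed=seed,
        n_strains=size,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def decay_summary(table: StrainParameterTable, p_assumed: float) -> DecaySummary:
    """Mean/min/max of per-strain ``1/lam = p*t0/(1-p)``, rounded to integers."""
    if not 0.0 < p_assumed < 1.0:
        raise ValueError(f"p_assumed must be in (0, 1), got {p_assumed!r}")
    tau = p_assumed * table.column("t0") / (1.0 - p_assumed)
    return DecaySummary(
        p=p_assumed,
        mean=int(round(float(tau.mean()))),
        minimum=int(round(float(tau.min()))),
        maximum=int(round(float(tau.max()))),
    )


def column_summary(table: StrainParameterTable) -> ColumnSummary:
    """Mean and (min, max) of t0, n and average RLS, to one decimal place."""

    def _stats(name: str) -> ColumnStats:
        col = table.column(name)
        return ColumnStats(
            mean=round(float(col.mean()), 1),
            minimum=round(float(col.min()), 1),
            maximum=round(float(col.max()), 1),
        )

    return ColumnSummary(t0=_stats("t0"), n=_stats("n"), avg_rls=_stats("avg_rls"))
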