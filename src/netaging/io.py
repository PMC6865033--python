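"""File formats and run configuration.

Lifespan data travel as long-format delimited text with a ``strain_id``
and ``lifespan`` column (comma or tab separated, header required, ``#``
comment lines allowed).  Fit tables are TSV with a fixed column order;
parameters are printed to 4 decimals and AIC to 2.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

import numpy as np

from .fitting import BootstrapSummary, LifespanDataset

__all__ = [
    "ParseError",
    "RunConfig",
    "FIT_TABLE_COLUMNS",
    "read_lifespans",
    "write_lifespans",
    "fit_table_row",
    "write_fit_table",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


FIT_TABLE_COLUMNS = [
    "strain",
    "n_obs",
    "avg_rls",
    "network_R",
    "network_R_sd",
    "t0",
    "t0_sd",
    "n",
    "n_sd",
    "gompertz_R",
    "gompertz_R_sd",
    "gompertz_G",
    "gompertz_G_sd",
    "weibull_aic",
    "weibull_aic_sd",
    "gompertz_aic",
    "gompertz_aic_sd",
    "network_aic",
    "network_aic_sd",
    "B",
    "seed",
]

_AIC_COLUMNS = {c for c in FIT_TABLE_COLUMNS if "aic" in c}


@dataclass(frozen=True)
class RunConfig:
    """Bundled run options; every output artifact records seed and B."""

    model: str = "all"
    bootstrap_B: int = 100
    seed: int | None = None
    restarts: int = 4
    tol: float = 1e-8
    p_assumed: float = 0.7
    input: str | None = None
    out: str | None = None
    verbose: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"config file {path} must hold a key/value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_lifespans(path, delimiter: str | None = None) -> list[LifespanDataset]:
    """Read long-format lifespans; one dataset per strain, in file order.

    Raises :class:`ParseError` naming the line number for missing columns,
    non-numeric or non-positive lifespans.
    """
    path = Path(path)
    groups: dict[str, list[float]] = {}
    header: list[str] | None = None
    idx_strain = idx_ls = -1
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if header is None:
                delim = delimiter or _sniff_delimiter(line)
                header = [c.strip().lower() for c in stripped.split(delim)]
                try:
                    idx_strain = header.index("strain_id")
                    idx_ls = header.index("lifespan")
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: header must contain "
                        "'strain_id' and 'lifespan' columns"
                    ) from None
                continue
            fields = [c.strip() for c in stripped.split(delim)]
            if len(fields) <= max(idx_strain, idx_ls):
                raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields")
            try:
                value = float(fields[idx_ls])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric lifespan {fields[idx_ls]!r}"
                ) from None
            if not np.isfinite(value) or value <= 0:
                raise ParseError(
                    f"{path}: line {lineno}: lifespan must be positive, got {value!r}"
                )
            groups.setdefault(fields[idx_strain], []).append(value)
    if not groups:
        raise ParseError(f"{path}: no data rows found")
    return [LifespanDataset(strain, values) for strain, values in groups.items()]


def write_lifespans(
    datasets: Iterable[LifespanDataset], path, comments: Sequence[str] = ()
) -> None:
    """Write datasets as ``strain_id,lifespan`` CSV (round-trip lossless)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh)
        writer.writerow(["strain_id", "lifespan"])
        for ds in datasets:
            for value in ds.lifespans:
                writer.writerow([ds.strain_id, repr(float(value))])


def fit_table_row(
    dataset: LifespanDataset,
    summaries: Mapping[str, BootstrapSummary],
    B: int,
    seed: int | None,
) -> dict:
    """Assemble one fit-table row from per-model bootstrap summaries."""
    row: dict = {c: "" for c in FIT_TABLE_COLUMNS}
    row.update(
        strain=dataset.strain_id, n_obs=dataset.n_obs, avg_rls=dataset.mean,
        B=B, seed="" if seed is None else seed,
    )
    net = summaries.get("network")
    if net is not None:
        row.update(
            network_R=net.means["R"], network_R_sd=net.sds["R"],
            t0=net.means["t0"], t0_sd=net.sds["t0"],
            n=net.means["n"], n_sd=net.sds["n"],
            network_aic=net.aic_mean, network_aic_sd=net.aic_sd,
        )
    gom = summaries.get("gompertz")
    if gom is not None:
        row.update(
            gompertz_R=gom.means["R"], gompertz_R_sd=gom.sds["R"],
            gompertz_G=gom.means["G"], gompertz_G_sd=gom.sds["G"],
            gompertz_aic=gom.aic_mean, gompertz_aic_sd=gom.aic_sd,
        )
    wei = summaries.get("weibull")
    if wei is not None:
        row.update(weibull_aic=wei.aic_mean, weibull_aic_sd=wei.aic_sd)
    return row


def _format_cell(column: str, value) -> str:
    if value == "" or isinstance(value, str):
        return str(value)
    if column in ("strain", "B", "seed", "n_obs"):
        return str(value)
    digits = 2 if column in _AIC_COLUMNS else 4
    return f"{float(value):.{digits}f}"


def write_fit_table(rows: Sequence[Mapping], path, comments: Sequence[str] = ()) -> None:
    """Write fit-table rows as TSV with the documented stable column order."""
    if not rows:
        raise ValueError("need at least one row")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(FIT_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(_format_cell(c, row.get(c, "")) for c in FIT_TABLE_COLUMNS)
                + "\n"
            )
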