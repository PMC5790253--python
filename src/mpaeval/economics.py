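"""Landings and income aggregation with consumer-price-index adjustment.

Fishery records (one row per year, optional month, species) are summed
to annual series per species scope.  Nominal income is put on a common
price basis with the consumer price index before the before-after fit.

Two deflation conventions are exposed:

``as-printed`` (default)
    ``I_t = RI * CPI_t / CPI_T`` — reported income times the ratio of
    that year's CPI to the reference (most recent) year's CPI.
``standard``
    ``I_t = RI * CPI_T / CPI_t`` — the conventional deflation to
    reference-year currency (the reciprocal ratio).

The default keeps fidelity with the published evaluation protocol;
the switch exists because conventional deflation inverts the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Sequence

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

ECON_COLUMNS = ("year", "month", "species", "landings_kg", "income")
DEFLATION_MODES = ("as-printed", "standard")


@dataclass
class CPISeries:
    """Annual consumer price index with a reference year."""

    values: dict[int, float]
    reference_year: int

    def __post_init__(self) -> None:
        self.values = {int(k): float(v) for k, v in self.values.items()}
        if self.reference_year not in self.values:
            raise ValidationError(
                f"reference year {self.reference_year} absent from CPI series"
            )
        if any(v <= 0 for v in self.values.values()):
            raise ValidationError("CPI values must be positive")

    def __getitem__(self, year: int) -> float:
        try:
            return self.values[int(year)]
        except KeyError:
            raise ValidationError(
                f"CPI series has no entry for year {year}"
            ) from None


def read_cpi(path, reference_year: int | None = None) -> CPISeries:
    """Read a CPI CSV with columns ``year, cpi``.

    The reference year defaults to the most recent year in the file.
    """
    df = pd.read_csv(path)
    if not {"year", "cpi"} <= set(df.columns):
        raise FormatError(f"{path}: CPI file needs columns 'year' and 'cpi'")
    values = dict(zip(df["year"].astype(int), df["cpi"].astype(float)))
    if reference_year is None:
        reference_year = max(values)
    return CPISeries(values=values, reference_year=reference_year)


def read_econ(path) -> pd.DataFrame:
    """Read landings/income records (year, optional month, species)."""
    df = pd.read_csv(path)
    missing = [c for c in ("year", "species", "landings_kg", "income")
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "month" not in df.columns:
        df["month"] = pd.NA
    df = df[list(ECON_COLUMNS)].copy()
    df["year"] = df["year"].astype(int)
    df["species"] = df["species"].astype(str)
    for col in ("landings_kg", "income"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if (df[col] < 0).any():
            row = int(df.index[df[col] < 0][0]) + 2
            raise ValidationError(f"{path}: row {row}: negative {col}")
    dup = df.duplicated(subset=["year", "month", "species"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (year, month, species) record(s) at data "
            f"row(s) {[int(i) + 2 for i in df.index[dup][:5]]}"
        )
    return df


def cpi_adjust(
    income_raw: float,
    cpi: CPISeries,
    year: int,
    deflation: str = "as-printed",
) -> float:
    """Inflation-adjust a nominal income figure (linear in income).

    Not idempotent: adjusting an already-adjusted figure rescales it
    again, so adjust exactly once.
    """
    if deflation not in DEFLATION_MODES:
        raise ValidationError(
            f"deflation must be one of {DEFLATION_MODES}, got {deflation!r}"
        )
    ratio = cpi[year] / cpi[cpi.reference_year]
    if deflation == "standard":
        ratio = 1.0 / ratio
    return income_raw * ratio


def aggregate_econ(
    records: pd.DataFrame,
    cpi: CPISeries | None = None,
    scope: str = "all",
    exclude: Sequence[str] = (),
    deflation: str = "as-printed",
) -> pd.DataFrame:
    """Sum landings and (CPI-adjusted) income to an annual series.

    Parameters
    ----------
    scope
        ``"all"`` or a single species code.
    exclude
        Species removed before aggregation (e.g. fisheries under an
        informal closure, which receive the same treatment in reserve
        and control and would dilute the contrast).

    Returns
    -------
    pandas.DataFrame
        Indexed by year, columns ``landings_kg`` and ``income``
        (adjusted when a CPI series is supplied, nominal otherwise).
    """
    d = records[~records["species"].isin(set(exclude))]
    if scope != "all":
        d = d[d["species"] == scope]
    if d.empty:
        raise ValidationError(
            f"no economic records left for scope {scope!r} after exclusions"
        )
    out = d.groupby("year")[["landings_kg", "income"]].sum().sort_index()
    if cpi is not None:
        out["income"] = [
            cpi_adjust(v, cpi, y, deflation=deflation)
            for y, v in out["income"].items()
        ]
    else:
        logger.info("no CPI series supplied; income left nominal")
    return out
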