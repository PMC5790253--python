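"""Reading, validation and sampling-design checks for monitoring inputs.

Underwater visual census data arrive as tidy CSV: one row per species
observation on one belt transect, with the environmental covariates
(bottom temperature, horizontal visibility, depth) recorded once per
transect.  A transect surveyed but empty is represented by a single row
with the reserved species code ``NONE`` and ``count`` 0, so that true
zero densities enter the regression rather than being silently dropped.

All per-transect quantities are expressed per transect; the package
does not assume specific transect dimensions, so per-area
standardization, if desired, is the caller's responsibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Reserved species code marking a surveyed-but-empty transect.
NONE_SPECIES = "NONE"

ZONES = ("control", "reserve")
TAXON_GROUPS = ("fish", "invertebrate")

#: Canonical survey column names (UTF-8, comma-separated, header row).
SURVEY_COLUMNS = (
    "site", "zone", "year", "transect", "group", "species",
    "count", "length_cm", "temperature", "visibility", "depth",
)
REQUIRED_SURVEY_COLUMNS = (
    "site", "zone", "year", "transect", "group", "species", "count",
)
COVARIATE_COLUMNS = ("temperature", "visibility", "depth")

TRAIT_COLUMNS = (
    "species", "group", "lw_a", "lw_b", "trophic_level",
    "length_at_maturity_cm", "common_name",
)

#: The seven canonical management objectives a reserve may declare.
OBJECTIVES = (
    "Avoid overexploitation",
    "Conserve species under special protection",
    "Maintain biological processes",
    "Improve fishery production in nearby waters",
    "Preserve biological diversity and the ecosystem",
    "Recover overexploited species",
    "Recover species of economic interest",
)

GOVERNANCE_CODES = tuple(f"G{i}" for i in range(1, 16)) + ("B5", "S3")


@dataclass
class ReserveConfig:
    """Reserve metadata needed to set up an evaluation run."""

    reserve_name: str
    implementation_year: int
    objectives: tuple[str, ...]
    target_species: tuple[str, ...] = ()
    excluded_species: tuple[str, ...] = ()
    reserve_size_km2: float | None = None

    def __post_init__(self) -> None:
        if not self.objectives:
            raise ValidationError("a reserve must declare at least one objective")
        canon = {o.lower(): o for o in OBJECTIVES}
        resolved = []
        for obj in self.objectives:
            key = obj.strip().lower()
            if key not in canon:
                raise ValidationError(
                    f"unknown objective {obj!r}; expected one of {list(OBJECTIVES)}"
                )
            resolved.append(canon[key])
        self.objectives = tuple(dict.fromkeys(resolved))
        self.target_species = tuple(dict.fromkeys(self.target_species))
        self.excluded_species = tuple(dict.fromkeys(self.excluded_species))


@dataclass
class GovernanceResponse:
    """One answer from the governance survey (codes G1-G15, B5, S3)."""

    code: str
    value: str | None = None
    narrative: str | None = None

    def __post_init__(self) -> None:
        if self.code not in GOVERNANCE_CODES:
            raise ValidationError(
                f"unknown governance code {self.code!r}; "
                f"expected one of {list(GOVERNANCE_CODES)}"
            )


@dataclass
class DesignReport:
    """Outcome of the sampling-design check.

    ``hard_failures`` block inference (no control zone, no pre- or
    post-implementation years); ``warnings`` flag soft issues such as
    site-years with fewer than the recommended 12 transects.
    """

    hard_failures: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    transect_counts: pd.DataFrame | None = None

    @property
    def passed(self) -> bool:
        return not self.hard_failures

    def summary(self) -> str:
        lines = ["design check: " + ("PASS" if self.passed else "FAIL")]
        lines += [f"  FAIL: {m}" for m in self.hard_failures]
        lines += [f"  warn: {m}" for m in self.warnings]
        return "\n".join(lines)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"found columns {list(df.columns)}"
        )


def read_surveys(path, traits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a transect-survey CSV.

    Parameters
    ----------
    path
        CSV with at least the columns
        ``site, zone, year, transect, group, species, count`` and
        optionally ``length_cm, temperature, visibility, depth``.
    traits
        Optional trait table (see :func:`read_traits`); species codes
        absent from it are reported but kept (they still contribute to
        richness, diversity and density).

    Returns
    -------
    pandas.DataFrame
        Validated records, original row numbers retained in the index
        offset (header is file row 1, first data row is file row 2).
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not parseable as CSV ({exc})") from exc
    _require_columns(df, REQUIRED_SURVEY_COLUMNS, path)
    for col in SURVEY_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[list(SURVEY_COLUMNS)].copy()
    return validate_surveys(df, traits=traits, source=str(path))


def validate_surveys(
    df: pd.DataFrame, traits: pd.DataFrame | None = None, source: str = "<memory>"
) -> pd.DataFrame:
    """Enforce field-level invariants on a survey table (in memory)."""
    df = df.copy()
    df["site"] = df["site"].astype(str)
    df["transect"] = df["transect"].astype(str)
    df["species"] = df["species"].astype(str)

    zone = df["zone"].astype(str).str.strip().str.lower()
    bad_zone = ~zone.isin(ZONES)
    if bad_zone.any():
        row = int(df.index[bad_zone][0]) + 2
        raise ValidationError(
            f"{source}: row {row}: zone {df['zone'][bad_zone].iloc[0]!r} "
            f"not one of {list(ZONES)}"
        )
    df["zone"] = zone

    group = df["group"].astype(str).str.strip().str.lower()
    bad_group = ~group.isin(TAXON_GROUPS)
    if bad_group.any():
        row = int(df.index[bad_group][0]) + 2
        raise ValidationError(
            f"{source}: row {row}: group {df['group'][bad_group].iloc[0]!r} "
            f"not one of {list(TAXON_GROUPS)}"
        )
    df["group"] = group

    try:
        df["year"] = df["year"].astype(int)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{source}: non-integer year value ({exc})") from exc

    count = pd.to_numeric(df["count"], errors="coerce")
    if count.isna().any():
        row = int(df.index[count.isna()][0]) + 2
        raise ValidationError(f"{source}: row {row}: count is not a number")
    if (count < 0).any():
        row = int(df.index[count < 0][0]) + 2
        raise ValidationError(f"{source}: row {row}: negative count")
    zero_real = (count == 0) & (df["species"] != NONE_SPECIES)
    if zero_real.any():
        row = int(df.index[zero_real][0]) + 2
        raise ValidationError(
            f"{source}: row {row}: count 0 is only allowed for the reserved "
            f"empty-transect code {NONE_SPECIES!r}"
        )
    df["count"] = count.astype(int)

    length = pd.to_numeric(df["length_cm"], errors="coerce")
    if ((length <= 0) & length.notna()).any():
        row = int(df.index[(length <= 0) & length.notna()][0]) + 2
        raise ValidationError(f"{source}: row {row}: non-positive length_cm")
    df["length_cm"] = length
    for col in COVARIATE_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    # Covariates are a property of the transect, not of the species row.
    keys = ["site", "zone", "year", "transect"]
    nun = df.groupby(keys)[list(COVARIATE_COLUMNS)].nunique(dropna=True)
    if (nun > 1).any().any():
        bad = nun[(nun > 1).any(axis=1)].index[0]
        raise ValidationError(
            f"{source}: covariates vary within transect {bad}; they must be "
            "constant per transect"
        )

    if traits is not None:
        known = set(traits["species"]) | {NONE_SPECIES}
        unknown = sorted(set(df["species"]) - known)
        if unknown:
            logger.warning(
                "%s: %d species code(s) absent from the trait table: %s "
                "(kept for richness/diversity/density; excluded from "
                "trait-dependent indicators)",
                source, len(unknown), unknown,
            )
    return df


def write_surveys(df: pd.DataFrame, path) -> None:
    """Write a survey table back to the canonical CSV dialect."""
    df.to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    """Read the species trait table (length-weight, trophic level, maturity).

    ``lw_a`` (g cm^-b) and ``lw_b`` parameterize the allometric
    length-weight conversion W = a L^b; values of ``lw_b`` outside
    [2, 4] are flagged as suspicious but accepted.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("species", "group"), path)
    for col in TRAIT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[list(TRAIT_COLUMNS)].copy()
    df["species"] = df["species"].astype(str)
    for col in ("lw_a", "lw_b", "trophic_level", "length_at_maturity_cm"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["lw_a"] <= 0).any() or (df["lw_b"] <= 0).any():
        raise ValidationError(f"{path}: length-weight coefficients must be positive")
    odd_b = df["lw_b"].notna() & ~df["lw_b"].between(2, 4)
    if odd_b.any():
        logger.warning(
            "%s: lw_b outside [2, 4] for %s — check units",
            path, list(df.loc[odd_b, "species"]),
        )
    if df["species"].duplicated().any():
        dup = list(df.loc[df["species"].duplicated(), "species"])
        raise ValidationError(f"{path}: duplicate trait rows for species {dup}")
    return df


def read_governance(path) -> list[GovernanceResponse]:
    """Read governance survey answers from JSON.

    Accepts either ``{"G5": "low", ...}`` or a list of objects
    ``[{"code": "G5", "value": "low", "narrative": "..."}, ...]``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    out: list[GovernanceResponse] = []
    if isinstance(raw, dict):
        for code, value in raw.items():
            if isinstance(value, dict):
                out.append(GovernanceResponse(code=code, **value))
            else:
                out.append(GovernanceResponse(code=code, value=str(value)))
    else:
        for item in raw:
            out.append(GovernanceResponse(**item))
    return out


def transect_units(df: pd.DataFrame) -> pd.DataFrame:
    """One row per surveyed transect with its covariates.

    The unit of observation for all indicators: the unique
    (site, zone, year, transect) combinations present in the records.
    """
    keys = ["site", "zone", "year", "transect"]
    return (
        df.groupby(keys, sort=True)[list(COVARIATE_COLUMNS)]
        .first()
        .reset_index()
    )


def validate_design(
    records: pd.DataFrame,
    config: ReserveConfig,
    min_transects: int = 12,
    post_from: str = "impl-year",
) -> DesignReport:
    """Check that the data support a before-after-control-impact fit.

    Hard failures: a single zone (no control), no pre-implementation
    years, or no post-implementation years — in any of these cases the
    interaction effect is unidentifiable and inference is blocked.
    Soft warnings: any site-year with fewer than ``min_transects``
    transects (12 is the commonly recommended minimum for this type of
    survey) and missing environmental covariates.

    Pure function: never mutates ``records``.
    """
    if records.empty:
        return DesignReport(hard_failures=["no survey records"])
    report = DesignReport()
    units = transect_units(records)

    zones = set(units["zone"])
    if "control" not in zones:
        report.hard_failures.append(
            "no control site: reserves without a control site and baseline "
            "cannot be evaluated"
        )
    if "reserve" not in zones:
        report.hard_failures.append("no reserve zone present in the data")

    boundary = _post_boundary(config.implementation_year, post_from)
    years = sorted(set(units["year"]))
    if not any(y < boundary for y in years):
        report.hard_failures.append(
            f"no pre-implementation baseline: all survey years {years} are on "
            f"or after the post-period start {boundary}"
        )
    if not any(y >= boundary for y in years):
        report.hard_failures.append(
            f"no post-implementation surveys: all survey years {years} "
            f"precede the post-period start {boundary}"
        )

    counts = (
        units.groupby(["site", "zone", "year"], sort=True)["transect"]
        .nunique()
        .rename("n_transects")
        .reset_index()
    )
    report.transect_counts = counts
    for _, row in counts[counts["n_transects"] < min_transects].iterrows():
        report.warnings.append(
            f"site {row['site']!r} ({row['zone']}, {row['year']}): only "
            f"{row['n_transects']} transects; at least {min_transects} per "
            "site per year are recommended"
        )
    for col in COVARIATE_COLUMNS:
        n_missing = int(units[col].isna().sum())
        if n_missing:
            report.warnings.append(
                f"covariate {col!r} missing on {n_missing}/{len(units)} transects"
            )
    return report


def _post_boundary(implementation_year: int, post_from: str) -> int:
    """First year counted as post-implementation."""
    if post_from == "impl-year":
        return implementation_year
    if post_from == "impl-year+1":
        return implementation_year + 1
    raise ValidationError(
        f"post_from must be 'impl-year' or 'impl-year+1', got {post_from!r}"
    )
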