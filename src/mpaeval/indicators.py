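"""Per-transect biological indicators.

Each indicator is one number per transect, the response variable of the
difference-in-differences regression:

======  =============================  =====================  ==========
code    indicator                      unit                   needs
======  =============================  =====================  ==========
B1      Shannon diversity index        (dimensionless, ln)    counts
B2      Species richness               species/transect       counts
B3      Density of mature organisms    percent of measured    lengths + maturity
B4      Density                        organisms/transect     counts
B6      Mean trophic level             (dimensionless)        counts + TL
B7      Biomass                        kg/transect            lengths + a, b
======  =============================  =====================  ==========

Fish and invertebrate communities are analyzed separately (B1, B2, B4
are each computed per taxon group); B3, B6 and B7 require fish lengths
and traits.  B4 and B7 additionally get one variant per declared target
species.  "Not measurable" propagates as NaN (the transect is excluded
from that indicator's fit), never as zero — conflating the two would
bias the regression.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .surveys import COVARIATE_COLUMNS, NONE_SPECIES, transect_units

logger = logging.getLogger(__name__)

BIOLOGICAL_INDICATORS = ("B1", "B2", "B3", "B4", "B6", "B7")
#: Indicators that admit a per-target-species variant.
TARGETABLE = ("B4", "B7")
#: Indicators computed per community (taxon group) rather than fish-only.
PER_GROUP = ("B1", "B2", "B4")

_KEYS = ["site", "zone", "year", "transect"]


# ---------------------------------------------------------------------------
# scalar building blocks (single transect)
# ---------------------------------------------------------------------------

def shannon_index(counts: Mapping[str, float]) -> float:
    """Shannon diversity H = -sum p_s ln p_s over observed species.

    Natural logarithm; ``H`` ranges from 0 (single species) to ln S
    (S equally abundant species).  Returns NaN for an empty transect
    (diversity of nothing is undefined, not zero).
    """
    c = np.array(
        [v for k, v in counts.items() if k != NONE_SPECIES and v > 0], dtype=float
    )
    if c.size == 0:
        return float("nan")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def species_richness(counts: Mapping[str, float]) -> int:
    """Number of distinct species with positive count (``NONE`` excluded)."""
    return sum(1 for k, v in counts.items() if k != NONE_SPECIES and v > 0)


def total_density(counts: Mapping[str, float], scope: str = "all") -> float:
    """Total organisms per transect, optionally restricted to one species."""
    if scope == "all":
        return float(sum(v for k, v in counts.items() if k != NONE_SPECIES))
    return float(counts.get(scope, 0))


def mature_fraction(lengths: Sequence[float], maturity_cm: float) -> float:
    """Percent of measured organisms at or above length at first maturity.

    Ties at exactly the maturity length count as mature.  Returns NaN
    when no lengths were recorded.
    """
    if maturity_cm <= 0:
        raise ValidationError("maturity_cm must be positive")
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        return float("nan")
    if (arr < 0).any():
        raise ValidationError("negative length")
    return float(100.0 * (arr >= maturity_cm).mean())


def mean_trophic_level(
    counts: Mapping[str, float], trophic: Mapping[str, float]
) -> float:
    """Abundance-weighted mean trophic level over species with a known TL.

    Species lacking a trophic-level trait are excluded (with a warning
    at table level); if none of the counted species has a TL the value
    is NaN.
    """
    num = den = 0.0
    for sp, n in counts.items():
        if sp == NONE_SPECIES or n <= 0:
            continue
        tl = trophic.get(sp)
        if tl is None or np.isnan(tl):
            continue
        num += n * tl
        den += n
    return num / den if den > 0 else float("nan")


def transect_biomass(
    observations: Iterable[tuple[str, float]],
    lw: Mapping[str, tuple[float, float]],
) -> float:
    """Total biomass on a transect in kg via W = a L^b (a in g cm^-b).

    ``observations`` is one (species, length_cm) pair per organism.
    Organisms without a length use the mean measured length of their
    species on the same transect when available; otherwise they are
    excluded.  An empty transect weighs 0 kg; observed organisms with
    no usable length-weight traits at all give NaN.
    """
    obs = list(observations)
    if not obs:
        return 0.0
    by_sp: dict[str, list[float]] = {}
    for sp, length in obs:
        if length is not None and not np.isnan(length):
            by_sp.setdefault(sp, []).append(float(length))
    grams = 0.0
    usable = 0
    for sp, length in obs:
        if sp not in lw:
            continue
        a, b = lw[sp]
        if length is None or np.isnan(length):
            if sp in by_sp:
                length = float(np.mean(by_sp[sp]))
            else:
                continue
        grams += a * float(length) ** b
        usable += 1
    if usable == 0:
        return float("nan")
    return grams / 1000.0


# ---------------------------------------------------------------------------
# vectorized table computation
# ---------------------------------------------------------------------------

def _presence(records: pd.DataFrame, group: str) -> pd.DataFrame:
    """Transect units on which the given taxon group was surveyed."""
    sub = records[records["group"] == group]
    return transect_units(sub)


def _emit(units: pd.DataFrame, values: pd.Series, indicator: str,
          community: str, scope: str) -> pd.DataFrame:
    out = units.merge(
        values.rename("value"), how="left", left_on=_KEYS, right_index=True
    )
    out.insert(0, "indicator", indicator)
    out.insert(1, "community", community)
    out.insert(2, "scope", scope)
    return out


def compute_indicator_table(
    records: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    indicators: Sequence[str] = BIOLOGICAL_INDICATORS,
    target_species: Sequence[str] = (),
) -> pd.DataFrame:
    """Compute the tidy per-transect indicator table.

    Returns one row per (indicator, community, scope, transect) with
    columns ``indicator, community, scope, site, zone, year, transect,
    temperature, visibility, depth, value``.  Community is the taxon
    group a community-level indicator refers to; scope is ``"all"`` or
    a target species code.  Indicators whose required traits are absent
    are skipped with a logged reason.
    """
    unknown = set(indicators) - set(BIOLOGICAL_INDICATORS)
    if unknown:
        raise ValidationError(
            f"unknown indicator code(s) {sorted(unknown)}; "
            f"expected among {list(BIOLOGICAL_INDICATORS)}"
        )
    live = records[records["species"] != NONE_SPECIES]
    sp_counts = (
        live.groupby(_KEYS + ["group", "species"], sort=False)["count"]
        .sum()
        .reset_index()
    )
    sp_group = dict(zip(live["species"], live["group"]))

    tr: dict[str, pd.Series] = {}
    if traits is not None:
        for col in ("trophic_level", "length_at_maturity_cm", "lw_a", "lw_b"):
            tr[col] = traits.set_index("species")[col]

    frames: list[pd.DataFrame] = []
    groups = [g for g in ("fish", "invertebrate") if (records["group"] == g).any()]

    for g in groups:
        units_g = _presence(records, g)
        cg = sp_counts[sp_counts["group"] == g]
        if "B4" in indicators:
            dens = cg.groupby(_KEYS)["count"].sum()
            frames.append(_emit(units_g, dens, "B4", g, "all"))
        if "B2" in indicators:
            rich = cg[cg["count"] > 0].groupby(_KEYS)["species"].nunique()
            frames.append(_emit(units_g, rich, "B2", g, "all"))
        if "B1" in indicators:
            pos = cg[cg["count"] > 0].copy()
            tot = pos.groupby(_KEYS)["count"].transform("sum")
            p = pos["count"] / tot
            pos["plogp"] = -p * np.log(p)
            h = pos.groupby(_KEYS)["plogp"].sum()
            ent = _emit(units_g, h, "B1", g, "all")
            # empty transects: diversity undefined, stays NaN
            frames.append(ent)
    # Fill structural zeros: an empty surveyed transect has density 0 and
    # richness 0, but undefined diversity.
    for f in frames:
        if len(f) and f["indicator"].iat[0] in ("B4", "B2"):
            f["value"] = f["value"].fillna(0)

    fish = records[records["group"] == "fish"]
    fish_live = fish[fish["species"] != NONE_SPECIES]
    units_fish = _presence(records, "fish") if "fish" in groups else None

    if "B6" in indicators and units_fish is not None:
        if "trophic_level" not in tr or tr["trophic_level"].dropna().empty:
            logger.warning("B6 skipped: no trophic_level traits available")
        else:
            d = fish_live.merge(
                tr["trophic_level"].rename("tl"), how="left",
                left_on="species", right_index=True,
            )
            no_tl = d["tl"].isna() & (d["count"] > 0)
            if no_tl.any():
                logger.warning(
                    "B6: species without trophic level excluded: %s",
                    sorted(set(d.loc[no_tl, "species"])),
                )
            d = d[d["tl"].notna()]
            num = (d["count"] * d["tl"]).groupby([d[k] for k in _KEYS]).sum()
            den = d.groupby(_KEYS)["count"].sum()
            frames.append(_emit(units_fish, num / den, "B6", "fish", "all"))

    if "B3" in indicators and units_fish is not None:
        mat = tr.get("length_at_maturity_cm")
        measured = fish_live[fish_live["length_cm"].notna()]
        if mat is None or mat.dropna().empty:
            logger.warning("B3 skipped: no length_at_maturity_cm traits available")
        elif measured.empty:
            logger.warning("B3 skipped: no fish lengths recorded")
        else:
            d = measured.merge(
                mat.rename("mat"), how="left", left_on="species", right_index=True
            )
            d = d[d["mat"].notna()]
            ismat = (d["length_cm"] >= d["mat"]).astype(float) * d["count"]
            num = ismat.groupby([d[k] for k in _KEYS]).sum()
            den = d.groupby(_KEYS)["count"].sum()
            frames.append(
                _emit(units_fish, 100.0 * num / den, "B3", "fish", "all")
            )

    if "B7" in indicators:
        frames.extend(
            _biomass_frames(records, sp_counts, tr, target_species, sp_group)
        )

    if "B4" in indicators:
        for sp in target_species:
            g = sp_group.get(sp)
            if g is None:
                logger.warning(
                    "B4 target %r skipped: species never observed", sp
                )
                continue
            units_g = _presence(records, g)
            dens = (
                sp_counts[sp_counts["species"] == sp]
                .groupby(_KEYS)["count"].sum()
            )
            f = _emit(units_g, dens, "B4", g, sp)
            f["value"] = f["value"].fillna(0)
            frames.append(f)

    if not frames:
        return pd.DataFrame(
            columns=["indicator", "community", "scope", *_KEYS,
                     *COVARIATE_COLUMNS, "value"]
        )
    out = pd.concat(frames, ignore_index=True)
    cols = ["indicator", "community", "scope", *_KEYS, *COVARIATE_COLUMNS, "value"]
    return out[cols].sort_values(
        ["indicator", "community", "scope", *_KEYS], ignore_index=True
    )


def _biomass_frames(records, sp_counts, tr, target_species, sp_group):
    """B7 rows (community fish + per-target variants)."""
    frames = []
    lw_a, lw_b = tr.get("lw_a"), tr.get("lw_b")
    have_lw = lw_a is not None and not lw_a.dropna().empty
    if not have_lw:
        logger.warning("B7 skipped: no length-weight traits available")
        return frames

    fish = records[(records["group"] == "fish")
                   & (records["species"] != NONE_SPECIES)]
    units_fish = _presence(records, "fish")
    if units_fish.empty:
        return frames

    d = fish.merge(lw_a.rename("a"), how="left", left_on="species",
                   right_index=True)
    d = d.merge(lw_b.rename("b"), how="left", left_on="species",
                right_index=True)
    d = d[d["a"].notna() & d["b"].notna()].copy()
    if d.empty:
        logger.warning("B7 skipped: no observed species has length-weight traits")
        return frames
    # impute species mean length within transect for unmeasured organisms
    meas = d[d["length_cm"].notna()]
    mean_len = (
        (meas["length_cm"] * meas["count"]).groupby(
            [meas[k] for k in _KEYS] + [meas["species"]]).sum()
        / meas.groupby(_KEYS + ["species"])["count"].sum()
    ).rename("mean_len")
    d = d.merge(mean_len, how="left", left_on=_KEYS + ["species"],
                right_index=True)
    d["use_len"] = d["length_cm"].fillna(d["mean_len"])
    n_dropped = int(d["use_len"].isna().sum())
    if n_dropped:
        logger.warning(
            "B7: %d record(s) without any length information excluded", n_dropped
        )
    d = d[d["use_len"].notna()]
    d["kg"] = d["count"] * d["a"] * d["use_len"] ** d["b"] / 1000.0

    def emit_biomass(sub, community, scope, units):
        kg = sub.groupby(_KEYS)["kg"].sum()
        f = _emit(units, kg, "B7", community, scope)
        # transects where fish were surveyed but none (with traits) seen: 0 kg
        f["value"] = f["value"].fillna(0.0)
        return f

    frames.append(emit_biomass(d, "fish", "all", units_fish))
    for sp in target_species:
        g = sp_group.get(sp)
        if g != "fish":
            continue  # no lengths for invertebrates; biomass not computable
        frames.append(emit_biomass(d[d["species"] == sp], "fish", sp, units_fish))
    return frames


def write_indicator_table(table: pd.DataFrame, path) -> None:
    """Write the tidy indicator table as CSV for external re-analysis."""
    table.to_csv(path, index=False)
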