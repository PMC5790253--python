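"""Synthetic BACI monitoring data with known ground truth.

The generator emulates a two-zone (reserve/control) annual underwater
visual census: per transect, each species' count is drawn from an
overdispersed negative-binomial model; fish get individual lengths;
every transect carries temperature, visibility and depth covariates.
A common multiplicative year effect moves both zones together, the
zone effect and the injected post-x-reserve interaction are additive
on the expected total count per transect (allocated across species in
proportion to their baseline means), so the injected shift *is* the
true difference-in-differences coefficient for total density and the
regression model is correctly specified.

Economic series are annual landings/income with a configurable
before/after level shift and a CPI path, constructed so the CPI-adjusted
income carries the injected shift in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .economics import CPISeries
from .errors import ValidationError
from .surveys import NONE_SPECIES

__all__ = [
    "SpeciesSim", "SimulationSpec", "simulate_baci", "simulate_econ",
    "make_fixture_bundle", "MINIMAL", "NATIVIDAD_LIKE", "COUNTS_ONLY",
]


@dataclass(frozen=True)
class SpeciesSim:
    """Ground-truth parameters for one simulated species."""

    code: str
    group: str  # fish | invertebrate
    mean_abundance: float  # expected organisms per transect
    dispersion: float = 5.0  # NB size parameter k; var = mu + mu^2/k
    mean_length_cm: float | None = None  # fish only
    sd_length_cm: float | None = None


# Default pools: a small temperate rocky-reef community.  Abundances are
# per 30 m belt transect, loosely scaled to the kinds of densities seen
# in community-monitored reefs (tens of urchins/snails, a few lobsters
# and cucumbers, a handful of fish per species).
DEFAULT_FISH = (
    SpeciesSim("sheephead", "fish", 4.0, 5.0, 28.0, 7.0),
    SpeciesSim("kelp_bass", "fish", 6.0, 5.0, 24.0, 6.0),
    SpeciesSim("senorita", "fish", 12.0, 4.0, 15.0, 4.0),
    SpeciesSim("garibaldi", "fish", 3.0, 6.0, 20.0, 5.0),
    SpeciesSim("opaleye", "fish", 5.0, 5.0, 22.0, 5.0),
)
DEFAULT_INVERTS = (
    SpeciesSim("lobster", "invertebrate", 3.0, 4.0),
    SpeciesSim("urchin", "invertebrate", 30.0, 3.0),
    SpeciesSim("snail", "invertebrate", 20.0, 3.0),
    SpeciesSim("cucumber", "invertebrate", 5.0, 4.0),
    SpeciesSim("sea_star", "invertebrate", 4.0, 5.0),
    SpeciesSim("keyhole_limpet", "invertebrate", 6.0, 5.0),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a simulated BACI survey program.

    ``transects_per_site_year`` may be an int (fixed effort) or a
    ``(low, high)`` tuple (effort drawn uniformly per site-year, as in
    real programs where weather limits dive days).  ``density_effect``
    is the additive post-x-reserve shift in expected organisms per
    transect within each taxon group — the true interaction
    coefficient of the group-level total-density indicator;
    ``species_effects`` injects additive shifts for single species.
    ``zone_shift`` is the analogous time-constant reserve offset.
    The seed fully determines the output.
    """

    years: tuple[int, ...] = tuple(range(2006, 2017))
    implementation_year: int = 2007
    transects_per_site_year: int | tuple[int, int] = 12
    species: tuple[SpeciesSim, ...] = DEFAULT_FISH + DEFAULT_INVERTS
    zone_shift: float = 5.0  # additive reserve-zone offset (organisms/transect)
    year_sigma: float = 0.08  # lognormal sd of the common year effect
    density_effect: float = 0.0  # injected true interaction, total density
    species_effects: dict[str, float] = field(default_factory=dict)
    temperature: tuple[float, float] = (18.0, 1.5)  # mean, sd (deg C)
    visibility: tuple[float, float] = (8.0, 2.0)  # mean, sd (m)
    depth: tuple[float, float] = (12.0, 3.0)  # mean, sd (m)
    post_from: str = "impl-year"
    seed: int = 0

    def __post_init__(self):
        if len(self.years) < 2:
            raise ValidationError("need at least two survey years")
        lo = self.years[0]
        hi = self.years[-1]
        if not (lo <= self.implementation_year <= hi + 1):
            raise ValidationError(
                f"implementation year {self.implementation_year} outside the "
                f"survey range {lo}-{hi}"
            )


MINIMAL = SimulationSpec(
    years=(2005, 2007),
    implementation_year=2006,
    transects_per_site_year=12,
)

#: Mimics an 11-year community monitoring program: variable effort
#: between 12 and 27 transects per site-year, a fish community plus
#: four harvested invertebrates, and positive injected effects on two
#: of them.
NATIVIDAD_LIKE = SimulationSpec(
    years=tuple(range(2006, 2017)),
    implementation_year=2007,
    transects_per_site_year=(12, 27),
    species_effects={"snail": 15.0, "cucumber": 2.0},
)

#: Invertebrate-only pool without lengths: compact records for large
#: replication studies of the count-based indicators.
COUNTS_ONLY = SimulationSpec(
    species=DEFAULT_INVERTS[:4],
    zone_shift=4.0,
)


def _n_transects(spec: SimulationSpec, rng) -> int:
    t = spec.transects_per_site_year
    if isinstance(t, int):
        if t < 1:
            raise ValidationError("transects_per_site_year must be >= 1")
        return t
    lo, hi = t
    return int(rng.integers(lo, hi + 1))


def _nb_draw(rng, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size ``k`` (Poisson as k→∞)."""
    mean = np.maximum(mean, 1e-9)
    p = k / (k + mean)
    return rng.negative_binomial(k, p)


def simulate_baci(spec: SimulationSpec) -> pd.DataFrame:
    """Generate a survey-record table for the given simulation spec.

    Returns records in the canonical survey schema (one row per
    invertebrate species-count or per individual fish with its length;
    empty group-surveys marked with the reserved ``NONE`` code).
    """
    rng = np.random.default_rng(spec.seed)
    boundary = (spec.implementation_year if spec.post_from == "impl-year"
                else spec.implementation_year + 1)
    group_mean = {
        g: sum(s.mean_abundance for s in spec.species if s.group == g)
        for g in {s.group for s in spec.species}
    }
    year_effect = {y: float(np.exp(rng.normal(0.0, spec.year_sigma)))
                   for y in spec.years}

    rows: list[dict] = []
    for zone in ("control", "reserve"):
        site = f"{zone}_site"
        for year in spec.years:
            n_tr = _n_transects(spec, rng)
            post = year >= boundary
            # additive offsets on each group's expected total, allocated
            # across that group's species proportional to baseline means
            offset = 0.0
            if zone == "reserve":
                offset += spec.zone_shift
                if post:
                    offset += spec.density_effect
            scale = {g: max(year_effect[year] + offset / m, 0.01)
                     for g, m in group_mean.items()}
            temp = rng.normal(*spec.temperature, size=n_tr)
            vis = np.clip(rng.normal(*spec.visibility, size=n_tr), 0.5, None)
            dep = np.clip(rng.normal(*spec.depth, size=n_tr), 1.0, None)
            counts = {}
            for s in spec.species:
                mu = s.mean_abundance * scale[s.group]
                extra = spec.species_effects.get(s.code, 0.0)
                if zone == "reserve" and post and extra:
                    mu = max(mu + extra, 1e-9)
                counts[s.code] = _nb_draw(rng, np.full(n_tr, mu), s.dispersion)
            for i in range(n_tr):
                transect = f"T{i + 1:02d}"
                base = {
                    "site": site, "zone": zone, "year": year,
                    "transect": transect, "temperature": round(temp[i], 2),
                    "visibility": round(vis[i], 2), "depth": round(dep[i], 2),
                }
                seen_group = {"fish": False, "invertebrate": False}
                for s in spec.species:
                    c = int(counts[s.code][i])
                    if c == 0:
                        continue
                    seen_group[s.group] = True
                    if s.group == "fish" and s.mean_length_cm is not None:
                        lengths = np.maximum(
                            rng.normal(s.mean_length_cm, s.sd_length_cm, c), 2.0
                        )
                        for length in lengths:
                            rows.append({**base, "group": "fish",
                                         "species": s.code, "count": 1,
                                         "length_cm": round(float(length), 1)})
                    else:
                        rows.append({**base, "group": s.group,
                                     "species": s.code, "count": c,
                                     "length_cm": np.nan})
                groups_present = {s.group for s in spec.species}
                for g in sorted(groups_present):
                    if not seen_group[g]:
                        rows.append({**base, "group": g,
                                     "species": NONE_SPECIES, "count": 0,
                                     "length_cm": np.nan})
    df = pd.DataFrame(rows)
    cols = ["site", "zone", "year", "transect", "group", "species",
            "count", "length_cm", "temperature", "visibility", "depth"]
    return df[cols]


def default_traits(spec: SimulationSpec = NATIVIDAD_LIKE) -> pd.DataFrame:
    """A trait table matching the simulated species pool."""
    rows = []
    for s in spec.species:
        fish = s.group == "fish"
        rows.append({
            "species": s.code,
            "group": s.group,
            "lw_a": 0.0126 if fish else np.nan,
            "lw_b": 3.04 if fish else np.nan,
            "trophic_level": {"sheephead": 3.7, "kelp_bass": 4.0,
                              "senorita": 3.2, "garibaldi": 2.8,
                              "opaleye": 2.4}.get(s.code, np.nan),
            "length_at_maturity_cm": (0.75 * s.mean_length_cm) if fish else np.nan,
            "common_name": s.code.replace("_", " "),
        })
    return pd.DataFrame(rows)


def simulate_econ(
    years,
    implementation_year: int,
    base_landings: float = 260.0,
    landings_shift: float = 0.0,
    base_income: float = 26000.0,
    income_shift: float = 0.0,
    noise: float = 0.05,
    inflation: float = 0.04,
    seed: int = 0,
    species: tuple[str, ...] = ("mixed",),
    post_from: str = "impl-year",
) -> tuple[pd.DataFrame, CPISeries]:
    """Annual landings/income records plus a CPI series.

    The before/after level shifts are injected on the *adjusted* scale
    in expectation: nominal income is back-computed through the CPI
    ratio so that adjustment recovers the target series.  ``noise`` is
    the relative (multiplicative Gaussian) noise level; 0 makes the
    shift exact.
    """
    years = tuple(int(y) for y in years)
    rng = np.random.default_rng(seed)
    ref = max(years)
    cpi = CPISeries(
        values={y: 100.0 * (1 + inflation) ** (y - ref) for y in years},
        reference_year=ref,
    )
    boundary = (implementation_year if post_from == "impl-year"
                else implementation_year + 1)
    rows = []
    for y in years:
        post = y >= boundary
        land_t = base_landings + (landings_shift if post else 0.0)
        inc_t = base_income + (income_shift if post else 0.0)
        for sp in species:
            land = (land_t / len(species)) * (1 + noise * rng.normal())
            inc = (inc_t / len(species)) * (1 + noise * rng.normal())
            # un-adjust so that the as-printed CPI adjustment recovers inc
            nominal = inc * cpi[ref] / cpi[y]
            rows.append({"year": y, "month": pd.NA, "species": sp,
                         "landings_kg": max(land, 0.0),
                         "income": max(nominal, 0.0)})
    return pd.DataFrame(rows, columns=["year", "month", "species",
                                       "landings_kg", "income"]), cpi


_GOVERNANCE_FIXTURE = {
    "G1": {"value": "turf"},
    "G2": {"value": "stable"},
    "G3": {"value": "no"},
    "G4": {"value": None, "narrative": "community-based marine reserve"},
    "G5": {"value": "low"},
    "G6": {"value": "no"},
    "G7": {"value": None,
           "narrative": "land stations with radar and 24/7 patrol boats"},
    "G8": {"value": "adequate"},
    "G9": {"value": None,
           "narrative": "sited on historically productive grounds chosen "
                        "with local knowledge"},
    "G10": {"value": "yes"},
    "G11": {"value": "federation"},
    "G12": {"value": "high"},
    "G13": {"value": "yes"},
    "G14": {"value": "positive"},
    "G15": {"value": "positive"},
    "S3": {"value": "few"},
    "B5": {"value": None,
           "narrative": "episodic hypoxia events affect invertebrates"},
}


def make_fixture_bundle(
    outdir: str | Path,
    preset: str = "minimal",
    seed: int = 0,
) -> dict[str, Path]:
    """Write a complete, loadable input bundle (synthetic throughout).

    Produces ``surveys.csv``, ``traits.csv``, ``econ.csv``, ``cpi.csv``,
    ``governance.json`` and a ready-to-run ``config.yaml``; the bundle
    round-trips through the CLI end to end.
    """
    import json

    presets = {"minimal": MINIMAL, "natividad_like": NATIVIDAD_LIKE}
    if preset not in presets:
        raise ValidationError(
            f"unknown preset {preset!r}; expected one of {sorted(presets)}"
        )
    spec = replace(presets[preset], seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    surveys = simulate_baci(spec)
    traits = default_traits(spec)
    econ, cpi = simulate_econ(
        spec.years, spec.implementation_year,
        landings_shift=30.0, income_shift=4000.0, seed=seed + 1,
        species=("lobster", "urchin", "snail", "cucumber"),
        post_from=spec.post_from,
    )

    paths = {
        "surveys": outdir / "surveys.csv",
        "traits": outdir / "traits.csv",
        "econ": outdir / "econ.csv",
        "cpi": outdir / "cpi.csv",
        "governance": outdir / "governance.json",
        "config": outdir / "config.yaml",
    }
    surveys.to_csv(paths["surveys"], index=False)
    traits.to_csv(paths["traits"], index=False)
    econ.to_csv(paths["econ"], index=False)
    pd.DataFrame({"year": sorted(cpi.values),
                  "cpi": [cpi.values[y] for y in sorted(cpi.values)]}
                 ).to_csv(paths["cpi"], index=False)
    paths["governance"].write_text(json.dumps(_GOVERNANCE_FIXTURE, indent=2))

    targets = [s.code for s in spec.species
               if s.code in ("lobster", "urchin", "snail", "cucumber")]
    config = {
        "surveys": "surveys.csv",
        "traits": "traits.csv",
        "econ": "econ.csv",
        "cpi": "cpi.csv",
        "governance": "governance.json",
        "output_dir": "results",
        "reserve": {
            "name": f"synthetic {preset} reserve",
            "implementation_year": spec.implementation_year,
            "objectives": [
                "Improve fishery production in nearby waters",
                "Preserve biological diversity and the ecosystem",
                "Recover overexploited species",
                "Recover species of economic interest",
            ],
            "target_species": targets,
            "excluded_species": [],
        },
        "options": {
            "robust": "HC1",
            "post_from": spec.post_from,
            "scoring": "sign",
            "deflation": "as-printed",
            "figures": True,
        },
    }
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths
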