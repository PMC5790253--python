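"""End-to-end evaluation pipeline: config in, scorecard and report out.

The six-step interactive workflow (objectives -> indicators -> data ->
reserve selection -> confirmation -> results) is replaced by a single
YAML configuration plus command-line overrides, which makes runs
scriptable and exactly reproducible: the evaluation path contains no
randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import economics, indicators, inference, scorecard as sc, surveys
from .errors import DesignError, MpaEvalError, ValidationError

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_RUNTIME = 1
EXIT_DESIGN = 2


@dataclass
class RunConfig:
    """Resolved configuration for one evaluation run."""

    surveys: Path
    traits: Path | None
    reserve: surveys.ReserveConfig
    econ: Path | None = None
    cpi: Path | None = None
    governance: Path | None = None
    rubric: Path | None = None
    output_dir: Path = Path("results")
    robust: str = "HC1"
    post_from: str = "impl-year"
    scoring: str = "sign"
    deflation: str = "as-printed"
    figures: bool = True
    override_design: bool = False
    indicator_selection: tuple[str, ...] | None = None


def load_run_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration; keyword overrides win."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(key):
        v = raw.get(key)
        return (base / v) if v else None

    res = raw.get("reserve", {})
    reserve = surveys.ReserveConfig(
        reserve_name=res.get("name", "unnamed reserve"),
        implementation_year=int(res["implementation_year"]),
        objectives=tuple(res.get("objectives", ())),
        target_species=tuple(res.get("target_species", ())),
        excluded_species=tuple(res.get("excluded_species", ())),
        reserve_size_km2=res.get("size_km2"),
    )
    opts = raw.get("options", {})
    cfg = RunConfig(
        surveys=resolve("surveys"),
        traits=resolve("traits"),
        econ=resolve("econ"),
        cpi=resolve("cpi"),
        governance=resolve("governance"),
        rubric=resolve("rubric"),
        reserve=reserve,
        output_dir=base / raw.get("output_dir", "results"),
        robust=opts.get("robust", "HC1"),
        post_from=opts.get("post_from", "impl-year"),
        scoring=opts.get("scoring", "sign"),
        deflation=opts.get("deflation", "as-printed"),
        figures=bool(opts.get("figures", True)),
    )
    for key, val in overrides.items():
        if val is not None:
            setattr(cfg, key, val)
    _validate_enums(cfg)
    return cfg


def _validate_enums(cfg: RunConfig) -> None:
    if cfg.robust not in inference.HC_FLAVORS:
        raise ValidationError(
            f"robust flavor {cfg.robust!r} not in {inference.HC_FLAVORS}")
    if cfg.post_from not in ("impl-year", "impl-year+1"):
        raise ValidationError(f"bad post_from {cfg.post_from!r}")
    if cfg.scoring not in sc.SCORING_MODES:
        raise ValidationError(f"bad scoring mode {cfg.scoring!r}")
    if cfg.deflation not in economics.DEFLATION_MODES:
        raise ValidationError(f"bad deflation mode {cfg.deflation!r}")
    if cfg.surveys is None:
        raise ValidationError("a surveys file is required")


def evaluate(cfg: RunConfig):
    """Run the full evaluation; returns (scorecard, effects, artifacts).

    Raises :class:`DesignError` on a hard sampling-design failure
    unless ``cfg.override_design`` is set.
    """
    traits = surveys.read_traits(cfg.traits) if cfg.traits else None
    records = surveys.read_surveys(cfg.surveys, traits=traits)

    report = surveys.validate_design(records, cfg.reserve,
                                     post_from=cfg.post_from)
    for msg in report.warnings:
        logger.warning("design: %s", msg)
    if not report.passed:
        if not cfg.override_design:
            raise DesignError("; ".join(report.hard_failures))
        logger.warning("design failures overridden: %s", report.hard_failures)

    selected = sc.indicators_for_objectives(cfg.reserve.objectives)
    if cfg.indicator_selection is not None:
        selected &= set(cfg.indicator_selection)
    bio_codes = tuple(c for c in indicators.BIOLOGICAL_INDICATORS
                      if c in selected)
    want_targets = {c[:-1] for c in selected if c.endswith("*")}

    table = indicators.compute_indicator_table(
        records, traits=traits, indicators=bio_codes,
        target_species=(cfg.reserve.target_species
                        if want_targets & set(indicators.TARGETABLE) else ()),
    )

    effects: list[inference.EffectEstimate] = []
    for (ind, comm, scope), sub in table.groupby(
            ["indicator", "community", "scope"]):
        if scope != "all" and f"{ind}*" not in selected:
            continue
        if scope == "all" and ind not in selected:
            continue
        try:
            effects.append(inference.did_effect(
                sub, cfg.reserve.implementation_year, cov_type=cfg.robust,
                post_from=cfg.post_from, indicator=ind, community=comm,
                scope=scope,
            ))
        except DesignError as exc:
            logger.warning("%s (%s, %s): not estimable: %s", ind, comm,
                           scope, exc)

    econ_series: dict[str, pd.Series] = {}
    if cfg.econ is not None:
        econ = economics.read_econ(cfg.econ)
        cpi = economics.read_cpi(cfg.cpi) if cfg.cpi else None
        scopes = ["all"]
        if {"S1*", "S2*"} & selected:
            scopes += [s for s in cfg.reserve.target_species
                       if s in set(econ["species"])]
        for scope in scopes:
            try:
                annual = economics.aggregate_econ(
                    econ, cpi=cpi, scope=scope,
                    exclude=cfg.reserve.excluded_species,
                    deflation=cfg.deflation,
                )
            except ValidationError as exc:
                logger.warning("economic scope %r skipped: %s", scope, exc)
                continue
            for code, col in (("S1", "landings_kg"), ("S2", "income")):
                starred = code if scope == "all" else f"{code}*"
                if starred not in selected:
                    continue
                series = annual[col]
                label = col if scope == "all" else f"{col}:{scope}"
                econ_series[label] = series
                try:
                    effects.append(inference.before_after_effect(
                        series, cfg.reserve.implementation_year,
                        cov_type=cfg.robust, post_from=cfg.post_from,
                        indicator=code, scope=scope,
                    ))
                except DesignError as exc:
                    logger.warning("%s (%s): not estimable: %s", code, scope,
                                   exc)

    governance = (surveys.read_governance(cfg.governance)
                  if cfg.governance else [])
    rubric = sc.load_rubric(cfg.rubric) if cfg.rubric else None

    card = sc.build_scorecard(effects, governance=governance, rubric=rubric,
                              mode=cfg.scoring)
    artifacts = sc.render_report(
        card, effects, config=cfg.reserve, outdir=cfg.output_dir,
        indicator_table=table, econ_series=econ_series, figures=cfg.figures,
    )
    return card, effects, artifacts


def run_evaluate(cfg: RunConfig) -> int:
    """CLI-facing wrapper: exit 0 on success, 2 on design failure, 1 else."""
    try:
        card, _, artifacts = evaluate(cfg)
    except DesignError as exc:
        logger.error("sampling design failure: %s", exc)
        return EXIT_DESIGN
    except MpaEvalError as exc:
        logger.error("%s", exc)
        return EXIT_RUNTIME
    except OSError as exc:
        logger.error("I/O failure: %s", exc)
        return EXIT_RUNTIME
    logger.info("global score %.0f%%; artifacts: %s", card.global_score,
                {k: str(v) for k, v in artifacts.items()})
    return EXIT_OK
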