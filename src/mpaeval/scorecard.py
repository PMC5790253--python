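"""Objective-indicator matching, color coding, and the effectiveness scorecard.

Numeric indicators are colored by the sign of the reserve-effect
coefficient and the significance of its Student-t test: dark green /
dark red when p < 0.05, green / red when 0.05 <= p < 0.1, and yellow
(no evidence of change) when p >= 0.1 or the coefficient is exactly
zero.  Governance indicators are colored red or green by a rubric of
factors the literature identifies as negative or positive for a
reserve; descriptive governance answers are passed through to the
report unscored.

Global and category scores are the percentage of positive indicators
among those scored.  By default "positive" means the effect direction
is positive regardless of significance; a strict mode counts only
effects significant at p < 0.1.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .inference import EffectEstimate
from .surveys import GOVERNANCE_CODES, OBJECTIVES, GovernanceResponse

logger = logging.getLogger(__name__)

#: Objective -> indicator selection.  Starred codes (e.g. ``B4*``) mean
#: "one variant per declared target species"; governance indicators are
#: implied for every objective and appended automatically.
OBJECTIVE_INDICATORS: dict[str, tuple[str, ...]] = {
    "Avoid overexploitation": (
        "B3", "B4", "B4*", "B5", "B6", "B7", "B7*",
        "S1", "S1*", "S2", "S2*", "S3",
    ),
    "Conserve species under special protection": (
        "B3", "B4*", "B5", "B7*", "S1", "S2", "S3",
    ),
    "Maintain biological processes": (
        "B1", "B2", "B4", "B5", "B6", "B7", "S3",
    ),
    "Improve fishery production in nearby waters": (
        "B4", "B4*", "B5", "B7", "B7*", "S1", "S1*", "S2", "S2*", "S3",
    ),
    "Preserve biological diversity and the ecosystem": (
        "B1", "B2", "B4", "B5", "B6", "B7", "S3",
    ),
    "Recover overexploited species": (
        "B3", "B4*", "B5", "B7*", "S1*", "S2*", "S3",
    ),
    "Recover species of economic interest": (
        "B3", "B4*", "B5", "B7*", "S1*", "S2*", "S3",
    ),
}

#: Governance codes whose answers are narrative-only: they appear in the
#: technical report but are never scored.
PASSTHROUGH_CODES = ("B5", "G4", "G7", "G9")

SCORING_MODES = ("sign", "strict")

_COLOR = {
    ("positive", "strong"): "dark_green",
    ("positive", "weak"): "green",
    ("negative", "strong"): "dark_red",
    ("negative", "weak"): "red",
}


def indicators_for_objectives(objectives) -> set[str]:
    """Union of indicator codes matched to the declared objectives.

    Always includes every governance indicator — each is a plausible
    explanatory variable for reserve performance whatever the
    objective.  The user may deselect indicators afterwards.
    """
    objectives = list(objectives)
    if not objectives:
        raise ValidationError("at least one objective is required")
    out: set[str] = set()
    for obj in objectives:
        match = next((k for k in OBJECTIVES if k.lower() == obj.strip().lower()),
                     None)
        if match is None:
            raise ValidationError(
                f"unknown objective {obj!r}; expected one of {list(OBJECTIVES)}"
            )
        out.update(OBJECTIVE_INDICATORS[match])
    out.update(c for c in GOVERNANCE_CODES if c.startswith("G"))
    return out


def color_for(beta: float, p: float) -> tuple[str, str, str]:
    """Map an effect estimate to (direction, intensity, color).

    Direction is the sign of the coefficient; intensity is ``strong``
    for p < 0.05, ``weak`` for 0.05 <= p < 0.1, ``none`` otherwise.
    Any non-significant effect (p >= 0.1) is yellow regardless of sign,
    as is an exactly zero coefficient.
    """
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if beta > 0:
        direction = "positive"
    elif beta < 0:
        direction = "negative"
    else:
        direction = "neutral"
    if p < 0.05:
        intensity = "strong"
    elif p < 0.1:
        intensity = "weak"
    else:
        intensity = "none"
    color = _COLOR.get((direction, intensity), "yellow")
    return direction, intensity, color


# ---------------------------------------------------------------------------
# governance rubric
# ---------------------------------------------------------------------------

def default_rubric() -> pd.DataFrame:
    """The rubric shipped with the package (editable default).

    A reconstruction of the commonly cited positive/negative governance
    factors for community-managed reserves; replace it with a custom
    CSV (columns ``code, level, color``) to change the scoring.
    """
    ref = importlib.resources.files("mpaeval") / "data" / "governance_rubric.csv"
    with importlib.resources.as_file(ref) as path:
        return load_rubric(path)


def load_rubric(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"code", "level", "color"} - set(df.columns)
    if missing:
        raise ValidationError(f"rubric lacks column(s) {sorted(missing)}")
    bad = set(df["color"]) - {"red", "green"}
    if bad:
        raise ValidationError(f"rubric colors must be red/green, got {bad}")
    df["level"] = df["level"].astype(str).str.strip().str.lower()
    return df


def governance_color(
    response: GovernanceResponse, rubric: pd.DataFrame
) -> str | None:
    """Red/green for a rubric-scored governance answer; None if passthrough.

    Raises for an answer level a scored code's rubric does not define,
    listing the allowed levels.
    """
    if response.code in PASSTHROUGH_CODES:
        return None
    rows = rubric[rubric["code"] == response.code]
    if rows.empty:
        logger.warning(
            "governance code %s has no rubric entries; passed through unscored",
            response.code,
        )
        return None
    if response.value is None:
        return None
    level = str(response.value).strip().lower().replace(" ", "_")
    hit = rows[rows["level"] == level]
    if hit.empty:
        raise ValidationError(
            f"{response.code}: level {response.value!r} not in rubric; "
            f"allowed levels: {sorted(rows['level'])}"
        )
    return str(hit["color"].iloc[0])


# ---------------------------------------------------------------------------
# scorecard
# ---------------------------------------------------------------------------

@dataclass
class IndicatorScore:
    """Color-coded evaluation of a single indicator."""

    indicator: str
    community: str
    scope: str
    category: str  # biological | socioeconomic | governance
    direction: str | None
    intensity: str | None
    color: str | None
    beta: float | None = None
    p: float | None = None
    scored: bool = True
    narrative: str | None = None

    @property
    def label(self) -> str:
        parts = [self.indicator]
        if self.community:
            parts.append(self.community)
        if self.scope and self.scope != "all":
            parts.append(self.scope)
        return ":".join(parts)


@dataclass
class Scorecard:
    """Global score, category scores and per-indicator colors."""

    global_score: float
    category_scores: dict[str, float]
    indicators: list[IndicatorScore]
    passthrough: list[IndicatorScore] = field(default_factory=list)
    scoring_mode: str = "sign"

    def to_dict(self) -> dict:
        return {
            "global": self.global_score,
            "categories": self.category_scores,
            "scoring_mode": self.scoring_mode,
            "indicators": [
                {
                    "label": s.label,
                    "indicator": s.indicator,
                    "community": s.community,
                    "scope": s.scope,
                    "category": s.category,
                    "direction": s.direction,
                    "intensity": s.intensity,
                    "color": s.color,
                    "beta": s.beta,
                    "p": s.p,
                }
                for s in self.indicators
            ],
            "passthrough": [
                {"label": s.label, "indicator": s.indicator,
                 "narrative": s.narrative}
                for s in self.passthrough
            ],
        }


def _positive(score: IndicatorScore, mode: str) -> bool:
    if score.category == "governance" or score.beta is None:
        return score.color == "green"
    if mode == "strict":
        return score.direction == "positive" and score.intensity != "none"
    return score.direction == "positive"


def build_scorecard(
    effects: list[EffectEstimate],
    governance: list[GovernanceResponse] = (),
    rubric: pd.DataFrame | None = None,
    mode: str = "sign",
) -> Scorecard:
    """Assemble the color-coded scorecard from fitted effects and answers.

    Scores are 100 x (positive indicators) / (scored indicators) per
    category and overall.  Indicators whose effect could not be
    estimated, and narrative governance answers, are excluded from the
    denominators (and listed as passthrough).
    """
    if mode not in SCORING_MODES:
        raise ValidationError(f"scoring mode must be one of {SCORING_MODES}")
    if rubric is None:
        rubric = default_rubric()

    scores: list[IndicatorScore] = []
    passthrough: list[IndicatorScore] = []
    for eff in effects:
        if eff.beta is None or pd.isna(eff.beta) or pd.isna(eff.p):
            passthrough.append(IndicatorScore(
                indicator=eff.indicator, community=eff.community,
                scope=eff.scope, category=eff.category, direction=None,
                intensity=None, color=None, scored=False,
            ))
            continue
        direction, intensity, color = color_for(eff.beta, eff.p)
        scores.append(IndicatorScore(
            indicator=eff.indicator, community=eff.community, scope=eff.scope,
            category=eff.category, direction=direction, intensity=intensity,
            color=color, beta=eff.beta, p=eff.p,
        ))
    for resp in governance:
        category = "socioeconomic" if resp.code == "S3" else (
            "biological" if resp.code == "B5" else "governance")
        color = governance_color(resp, rubric)
        if color is None:
            passthrough.append(IndicatorScore(
                indicator=resp.code, community="", scope="all",
                category=category, direction=None, intensity=None,
                color=None, scored=False, narrative=resp.narrative or resp.value,
            ))
            continue
        scores.append(IndicatorScore(
            indicator=resp.code, community="", scope="all", category=category,
            direction="positive" if color == "green" else "negative",
            intensity=None, color=color, narrative=resp.narrative,
        ))

    if not scores:
        raise ValidationError("no scored indicators: nothing to summarize")

    def pct(items: list[IndicatorScore]) -> float:
        if not items:
            return float("nan")
        return 100.0 * sum(_positive(s, mode) for s in items) / len(items)

    categories = {}
    for cat in ("biological", "socioeconomic", "governance"):
        members = [s for s in scores if s.category == cat]
        if members:
            categories[cat] = pct(members)
    return Scorecard(
        global_score=pct(scores),
        category_scores=categories,
        indicators=scores,
        passthrough=passthrough,
        scoring_mode=mode,
    )


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_report(
    scorecard: Scorecard,
    effects: list[EffectEstimate],
    config=None,
    outdir: str | Path = "results",
    indicator_table: pd.DataFrame | None = None,
    econ_series: dict[str, pd.Series] | None = None,
    figures: bool = True,
) -> dict[str, Path]:
    """Write the machine- and human-readable evaluation report.

    Produces ``scorecard.json``, ``report.md``, a tidy
    ``coefficients.csv`` (one row per model term per indicator), and —
    when ``figures`` is true — one time-series plot per indicator
    (yearly mean with a +/- 1 standard error ribbon per zone, jittered
    transect points).  Output is deterministic: no timestamps are
    embedded, so re-rendering identical inputs is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    json_path = outdir / "scorecard.json"
    json_path.write_text(json.dumps(scorecard.to_dict(), indent=2,
                                    sort_keys=True) + "\n")
    artifacts["scorecard"] = json_path

    rows = []
    for eff in effects:
        if eff.fit is None:
            continue
        label = ":".join(x for x in (eff.indicator, eff.community) if x)
        if eff.scope != "all":
            label += f":{eff.scope}"
        tab = eff.fit.coef_table()
        tab.insert(0, "indicator", label)
        tab["n"] = eff.fit.nobs
        tab["r_squared"] = eff.fit.rsquared
        rows.append(tab)
    coef_path = outdir / "coefficients.csv"
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(coef_path, index=False,
                                                  float_format="%.6g")
        artifacts["coefficients"] = coef_path

    plot_paths: dict[str, Path] = {}
    if figures and indicator_table is not None and len(indicator_table):
        plot_paths = _plot_indicators(indicator_table, outdir / "plots")
    if figures and econ_series:
        plot_paths.update(_plot_econ(econ_series, outdir / "plots"))
    artifacts.update(plot_paths)

    md_path = outdir / "report.md"
    md_path.write_text(_markdown_report(scorecard, effects, config, plot_paths))
    artifacts["report"] = md_path
    return artifacts


def _markdown_report(scorecard, effects, config, plot_paths) -> str:
    name = getattr(config, "reserve_name", "reserve") if config else "reserve"
    lines = [
        f"# Reserve effectiveness report — {name}",
        "",
        f"**Global score: {scorecard.global_score:.0f}%** of scored "
        "indicators positive "
        f"(scoring mode: {scorecard.scoring_mode}).",
        "",
        "| category | score |",
        "|---|---|",
    ]
    for cat, val in scorecard.category_scores.items():
        lines.append(f"| {cat} | {val:.0f}% |")
    lines += ["", "## Indicators", "",
              "| indicator | category | effect | p | color |", "|---|---|---|---|---|"]
    for s in scorecard.indicators:
        beta = "" if s.beta is None else f"{s.beta:.4g}"
        p = "" if s.p is None else f"{s.p:.4g}"
        lines.append(f"| {s.label} | {s.category} | {beta} | {p} | {s.color} |")
    if scorecard.passthrough:
        lines += ["", "## Descriptive entries (not scored)", ""]
        for s in scorecard.passthrough:
            lines.append(f"- **{s.label}**: {s.narrative or 'not estimable'}")
    lines += ["", "## Regression summaries", ""]
    for eff in effects:
        if eff.fit is None:
            continue
        label = ":".join(x for x in (eff.indicator, eff.community) if x)
        if eff.scope != "all":
            label += f":{eff.scope}"
        causal = "difference-in-differences" if eff.model == "did" else \
            "before-after (not causal)"
        lines.append(
            f"### {label}\n\n{causal}; n = {eff.fit.nobs}, "
            f"R² = {eff.fit.rsquared:.3f}\n"
        )
        tab = eff.fit.coef_table()
        lines.append("| term | estimate | robust SE | t | p |")
        lines.append("|---|---|---|---|---|")
        for _, r in tab.iterrows():
            lines.append(
                f"| {r['term']} | {r['estimate']:.4g} | {r['robust_se']:.4g} "
                f"| {r['t']:.4f} | {r['p']:.4g} |"
            )
        lines.append("")
    if plot_paths:
        lines += ["## Figures", ""]
        for label, path in sorted(plot_paths.items()):
            lines.append(f"- {label}: `{path.name}`")
    return "\n".join(lines) + "\n"


def _plot_indicators(table: pd.DataFrame, plotdir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    plotdir.mkdir(parents=True, exist_ok=True)
    out = {}
    zcol = {"reserve": "tab:red", "control": "tab:blue"}
    for (ind, comm, scope), sub in table.groupby(
            ["indicator", "community", "scope"]):
        label = ":".join(x for x in (ind, comm) if x)
        if scope != "all":
            label += f":{scope}"
        fig, ax = plt.subplots(figsize=(6, 3.5))
        rng = np.random.default_rng(0)  # jitter only; fixed for determinism
        for zone, zsub in sub.groupby("zone"):
            stats = zsub.groupby("year")["value"].agg(["mean", "sem"])
            ax.plot(stats.index, stats["mean"], color=zcol.get(zone, "k"),
                    label=zone)
            ax.fill_between(stats.index, stats["mean"] - stats["sem"],
                            stats["mean"] + stats["sem"],
                            color=zcol.get(zone, "k"), alpha=0.2, lw=0)
            jitter = rng.uniform(-0.15, 0.15, len(zsub))
            ax.scatter(zsub["year"] + jitter, zsub["value"], s=6,
                       color=zcol.get(zone, "k"), alpha=0.35)
        ax.set_xlabel("year")
        ax.set_ylabel(label)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fname = plotdir / (label.replace(":", "_") + ".png")
        fig.savefig(fname, dpi=110)
        plt.close(fig)
        out[f"plot:{label}"] = fname
    return out


def _plot_econ(series: dict[str, pd.Series], plotdir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for label, s in series.items():
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(s.index, s.values, marker="o", ms=3, color="tab:purple")
        ax.set_xlabel("year")
        ax.set_ylabel(label)
        fig.tight_layout()
        fname = plotdir / (label.replace(":", "_") + ".png")
        fig.savefig(fname, dpi=110)
        plt.close(fig)
        out[f"plot:{label}"] = fname
    return out
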