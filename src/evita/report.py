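"""Combining efficiency and risk into the EVITA score, banding it, and
rendering reports.

The EVITA score is the sum of the efficiency score and the net risk
score, bounded by construction to [-25, +25].  Because exact point values
would suggest more precision than the rubric provides, the score is
displayed as a color-coded bar: green for clearly positive totals, red
for clearly negative ones and yellow for values around zero.  When no
eligible trial exists the verdict is an explicit "calculation not
available" (N/A), rendered as a yield sign — an assessment result in its
own right, not an error.
"""

from __future__ import annotations

import enum
import itertools
import json
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .efficiency import (
    MODIFIER_VALUES,
    EfficiencyResult,
    base_points,
    efficiency_score,
)
from .eligibility import (
    SettingValue,
    TrialSetting,
    classify_trial_setting,
    filter_trials,
)
from .model import (
    ArmRiskProfile,
    AssessmentDossier,
    FrequencyClass,
    InteractionClass,
    OutcomeLevel,
    ScoringOptions,
    TherapeuticContext,
)
from .risk import RiskResult, arm_sum, risk_score

__all__ = [
    "Band",
    "EvitaResult",
    "InternalConsistencyError",
    "combine",
    "color_band",
    "score_bounds",
    "evaluate",
    "render_report",
]

SCORE_MIN = -25.0
SCORE_MAX = 25.0
DEFAULT_YELLOW_HALF_WIDTH = 2.0

REPORT_SCHEMA_VERSION = 1


class Band(str, enum.Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"
    NOT_ASSESSABLE = "not_assessable"


class InternalConsistencyError(RuntimeError):
    """A computed total escaped the provable [-25, +25] envelope — this
    indicates a defect in one of the scoring tables, never bad input."""


class EvitaResult(BaseModel):
    """Full assessment outcome, including the audit trail."""

    model_config = ConfigDict(frozen=True)

    context: TherapeuticContext
    setting: TrialSetting
    efficiency: Optional[EfficiencyResult] = None
    risk: Optional[RiskResult] = None
    total: Optional[float] = None
    band: Band

    @property
    def assessable(self) -> bool:
        return self.band != Band.NOT_ASSESSABLE


def combine(efficiency: EfficiencyResult, risk: RiskResult) -> float:
    """EVITA total: reported efficiency score plus net risk score."""
    total = efficiency.reported_score + risk.net_score
    if not SCORE_MIN - 1e-9 <= total <= SCORE_MAX + 1e-9:
        raise InternalConsistencyError(
            f"total {total} outside [{SCORE_MIN}, {SCORE_MAX}]"
        )
    return total


def color_band(total: float, yellow_half_width: Optional[float] = None) -> Band:
    """Traffic-light band for an assessable total.

    Totals within ``yellow_half_width`` of zero (default 2.0 points) are
    yellow (inconclusive); above that green, below red.  The band is pure
    presentation and never feeds back into the arithmetic.
    """
    w = DEFAULT_YELLOW_HALF_WIDTH if yellow_half_width is None else yellow_half_width
    if abs(total) <= w:
        return Band.YELLOW
    return Band.GREEN if total > 0 else Band.RED


def score_bounds() -> tuple[float, float]:
    """Extreme EVITA totals, by brute-force enumeration of the tables.

    Enumerates every admissible efficiency configuration (trial counts 0,
    1 and >=2 per result direction, both outcome levels, every modifier
    band plus the no-NNT case) and every per-arm risk configuration (all
    frequency classes per severity group crossed with all interaction
    classes, for both arms), rather than trusting a closed-form argument.
    """
    base_sums = {
        base_points(s, n, i, level)
        for s, n, i in itertools.product((0, 1, 2), repeat=3)
        for level in OutcomeLevel
    }
    factors = set(MODIFIER_VALUES) | {1.0}  # 1.0 also covers "no NNT available"
    eff_values = {b * f for b in base_sums for f in factors}

    classes = list(FrequencyClass)
    arm_values = {
        arm_sum(
            ArmRiskProfile(
                arm_label="enum",
                grade_4_5_freq=g45,
                grade_3_freq=g3,
                grade_1_2_freq=g12,
                interaction_class=inter,
            )
        )
        for g45, g3, g12, inter in itertools.product(
            classes, classes, classes, list(InteractionClass)
        )
    }
    net_values = {d - c for d in arm_values for c in arm_values}

    totals = [e + n for e in eff_values for n in net_values]
    return (min(totals), max(totals))


def evaluate(
    dossier: AssessmentDossier, options: Optional[ScoringOptions] = None
) -> EvitaResult:
    """Run the full pipeline: filter trials, classify the setting, score
    efficiency and risk, combine and band.

    ``options`` overrides the dossier's own scoring options.
    """
    options = options or dossier.options
    included, excluded = filter_trials(dossier.trials, dossier.context)
    setting = classify_trial_setting(included, dossier.context, excluded)
    if setting.value == SettingValue.NA:
        return EvitaResult(
            context=dossier.context,
            setting=setting,
            band=Band.NOT_ASSESSABLE,
        )
    eff = efficiency_score(included, dossier.context, options)
    rsk = risk_score(dossier.drug_risk, dossier.comparator_risk)
    total = combine(eff, rsk)
    return EvitaResult(
        context=dossier.context,
        setting=setting,
        efficiency=eff,
        risk=rsk,
        total=total,
        band=color_band(total, options.yellow_half_width),
    )


# ---------------------------------------------------------------------------
# rendering

_BAND_COLORS = {Band.GREEN: "#2e7d32", Band.YELLOW: "#f9a825", Band.RED: "#c62828"}


def result_to_dict(result: EvitaResult) -> dict:
    doc = result.model_dump(mode="json", exclude_none=True)
    doc["report_schema_version"] = REPORT_SCHEMA_VERSION
    return doc


def _render_json(result: EvitaResult) -> str:
    return json.dumps(result_to_dict(result), indent=2)


def _svg_bar(result: EvitaResult) -> str:
    """Horizontal score bar on a fixed -25..+25 axis, or a yield sign for
    N/A, so positions are visually comparable across drugs."""
    width, height, margin = 560, 120, 30
    axis_y = 70
    scale = (width - 2 * margin) / (SCORE_MAX - SCORE_MIN)

    def x(v: float) -> float:
        return margin + (v - SCORE_MIN) * scale

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<text x="{margin}" y="20" font-family="sans-serif" font-size="14">'
        f"{result.context.drug_name} — {result.context.indication} "
        f"(aim: {result.context.therapeutic_aim.value}, "
        f"category {result.context.disease_category.value}, "
        f"setting {result.setting.value.value})</text>",
    ]
    if result.assessable and result.total is not None:
        color = _BAND_COLORS[result.band]
        x0, x1 = sorted((x(0.0), x(result.total)))
        bar_w = max(x1 - x0, 1.5)
        parts += [
            f'<line x1="{x(SCORE_MIN)}" y1="{axis_y}" x2="{x(SCORE_MAX)}" y2="{axis_y}" '
            'stroke="#444" stroke-width="1"/>',
            f'<rect x="{x0:.1f}" y="{axis_y - 16}" width="{bar_w:.1f}" height="32" '
            f'fill="{color}" fill-opacity="0.85"/>',
            f'<line x1="{x(0.0)}" y1="{axis_y - 22}" x2="{x(0.0)}" y2="{axis_y + 22}" '
            'stroke="#000" stroke-width="1"/>',
        ]
        for tick in (-25, -20, -15, -10, -5, 0, 5, 10, 15, 20, 25):
            parts.append(
                f'<text x="{x(tick):.1f}" y="{axis_y + 38}" font-family="sans-serif" '
                f'font-size="10" text-anchor="middle">{tick}</text>'
            )
        parts.append(
            f'<text x="{x(result.total):.1f}" y="{axis_y - 24}" font-family="sans-serif" '
            f'font-size="13" text-anchor="middle" font-weight="bold">{result.total:+g}</text>'
        )
    else:
        # Yield sign with a question mark: score not computable.
        cx = width / 2
        parts += [
            f'<polygon points="{cx - 40},{axis_y - 30} {cx + 40},{axis_y - 30} {cx},{axis_y + 38}" '
            'fill="#fff" stroke="#c62828" stroke-width="6"/>',
            f'<text x="{cx}" y="{axis_y + 4}" font-family="sans-serif" font-size="30" '
            'text-anchor="middle" font-weight="bold">?</text>',
            f'<text x="{cx}" y="{height - 4}" font-family="sans-serif" font-size="12" '
            'text-anchor="middle">EVITA calculation not available (N/A)</text>',
        ]
    parts.append("</svg>")
    return "\n".join(parts)


def _render_html(result: EvitaResult) -> str:
    ctx = result.context
    if result.assessable and result.efficiency and result.risk:
        score_block = (
            f"<p class='score'>EVITA score: <b>{result.total:+g}</b> "
            f"(band: {result.band.value})</p>"
            f"<p>Efficiency {result.efficiency.reported_score:+g} "
            f"(base {result.efficiency.base_sum:+g}, modifier "
            f"{result.efficiency.modifier if result.efficiency.modifier is not None else '—'}), "
            f"net risk {result.risk.net_score:+g} "
            f"(drug {result.risk.drug_sum:+g} vs comparator {result.risk.comparator_sum:+g}).</p>"
        )
    else:
        score_block = "<p class='score'><b>N/A</b> — EVITA calculation not available.</p>"
    exclusions = "".join(
        f"<li>{e.trial_id}: {e.reason}</li>" for e in result.setting.excluded_trials
    ) or "<li>none</li>"
    inclusions = "".join(f"<li>{t}</li>" for t in result.setting.included_trials) or "<li>none</li>"
    return f"""<!DOCTYPE html>
<html lang="en">
<head><meta charset="utf-8"><title>EVITA report: {ctx.drug_name}</title>
<style>body{{font-family:sans-serif;max-width:42em;margin:2em auto}}
.score{{font-size:1.2em}}</style></head>
<body>
<h1>{ctx.drug_name}</h1>
<p>{ctx.indication} — therapeutic aim: <b>{ctx.therapeutic_aim.value}</b>,
disease category <b>{ctx.disease_category.value}</b>,
trial setting <b>{result.setting.value.value}</b></p>
{score_block}
{_svg_bar(result)}
<h2>Included trials</h2><ul>{inclusions}</ul>
<h2>Excluded trials</h2><ul>{exclusions}</ul>
</body>
</html>
"""


def render_report(result: EvitaResult, format: str = "json") -> str:
    """Render a report document.

    ``json`` carries every intermediate value and exclusion reason;
    ``html`` is a self-contained page with the score bar embedded;
    ``svg`` is the bar (or yield sign) alone.
    """
    renderers = {"json": _render_json, "html": _render_html, "svg": _svg_bar}
    try:
        renderer = renderers[format]
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; expected one of {sorted(renderers)}"
        ) from None
    return renderer(result)
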