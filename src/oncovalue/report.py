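"""Human-readable reports mirroring the framework's six-step scorecard layout.

Markdown output shows the intermediate arithmetic of every step; CSV output
carries separator-free machine-readable numbers that round-trip exactly to
the scorecard values.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .economics import ValueScorecard


def _num(x: float) -> str:
    """Render a number without trailing noise: 34.0 -> '34', -4.54 -> '-4.54'."""
    if x == int(x):
        return str(int(x))
    return f"{x:.10g}"


def _cop(x: float) -> str:
    """Whole-COP amount with #,### thousands separators."""
    return f"{int(round(x)):,}"


RUNG_LABELS = {
    "1.A": "death hazard ratio",
    "1.B": "median overall survival",
    "1.C": "progression hazard ratio",
    "1.D": "median progression-free survival",
    "1.E": "response rate",
}


def _step1_arithmetic(prov: dict, cb: float) -> str:
    eff = prov.get("efficacy", {})
    rung = prov.get("benefit_rung", "?")
    if rung == "1.A" and "death_hr" in eff:
        hr = eff["death_hr"]["point"]
        return f"(1 − {_num(hr)}) × 100 = {_num(cb)}"
    if rung == "1.C" and "progression_hr" in eff:
        hr = eff["progression_hr"]["point"]
        return f"(1 − {_num(hr)}) × 100 × 0.8 = {_num(cb)}"
    if rung == "1.B" and "median_os" in eff:
        e = eff["median_os"]
        return (
            f"100 × ({_num(e['median_test'])} − {_num(e['median_comparator'])}) / "
            f"{_num(e['median_comparator'])} = {_num(cb)}"
        )
    if rung == "1.D" and "median_pfs" in eff:
        e = eff["median_pfs"]
        return (
            f"100 × ({_num(e['median_test'])} − {_num(e['median_comparator'])}) / "
            f"{_num(e['median_comparator'])} × 0.8 = {_num(cb)}"
        )
    if rung == "1.E" and "response" in eff:
        e = eff["response"]
        return f"100 × ({_num(e['rr_test'])} − {_num(e['rr_comparator'])}) × 0.7 = {_num(cb)}"
    return _num(cb)


def render_stepwise(card: ValueScorecard) -> str:
    """Render one scorecard as a six-step markdown report."""
    prov = card.provenance
    nhb = card.nhb
    tt = prov["toxicity_points_test"]
    tc = prov["toxicity_points_comparator"]
    lines = [
        f"# Value scorecard — {card.trial_name} ({card.regimen_name})",
        "",
        f"Config hash: `{prov['config_hash']}`",
        "",
        "## Step 1: Clinical benefit",
        f"- Rung used: {prov['benefit_rung']} ({RUNG_LABELS.get(prov['benefit_rung'], '?')})",
        f"- Arithmetic: {_step1_arithmetic(prov, nhb.clinical_benefit)}",
        f"- Clinical benefit score: {_num(nhb.clinical_benefit)}",
        "",
        "## Step 2: Toxicity",
        f"- Adverse-event point totals: test {_num(tt)}, comparator {_num(tc)}",
        f"- Arithmetic: (1 − {_num(tt)}/{_num(tc)}) × 20 = {_num(prov['toxicity_score_computed'])}",
        f"- Toxicity score used ({prov['toxicity_source']}): {_num(nhb.toxicity_score)}",
    ]
    if prov.get("toxicity_conflict"):
        lines.append(
            f"- WARNING: reported score {_num(prov['toxicity_score_reported'])} disagrees "
            f"with the computed score {_num(prov['toxicity_score_computed'])}"
        )
    b = nhb.bonus
    lines += [
        "",
        "## Step 3: Bonus points",
        f"- Tail of the curve: {_num(b.tail_points)} ({prov['tail_reason']})",
        f"- Palliation of symptoms: {_num(b.palliation_points)}",
        f"- Quality of life: {_num(b.qol_points)}",
        f"- Treatment-free interval: {_num(b.tfi_points)}",
        f"- Total bonus: {_num(b.total)}",
        "",
        "## Step 4: Net health benefit",
        f"- {_num(nhb.clinical_benefit)} + ({_num(nhb.toxicity_score)}) + {_num(b.total)} "
        f"= {_num(nhb.nhb)} (of {_num(nhb.max_possible)} possible)",
        "",
        "## Step 5: Monthly drug cost",
        f"- {_cop(card.monthly_cost)} COP ({card.monthly_cost_usd:.2f} USD), "
        f"{prov['tablets_per_month']} tablets/month",
        "",
        "## Step 6: Summary",
        "",
        "| Clinical benefit | Toxicity | Bonus | NHB | Monthly cost (COP) | Cost per NHB point (COP) |",
        "|---|---|---|---|---|---|",
        f"| {_num(nhb.clinical_benefit)} | {_num(nhb.toxicity_score)} | {_num(b.total)} "
        f"| {_num(nhb.nhb)} | {_cop(card.monthly_cost)} | {_cop(card.cost_per_point)} |",
        "",
    ]
    return "\n".join(lines)


SCORECARD_COLUMNS = [
    "trial_name",
    "regimen_name",
    "clinical_benefit",
    "toxicity_score",
    "bonus_total",
    "nhb",
    "monthly_cost_cop",
    "monthly_cost_usd",
    "cost_per_point_cop",
    "cost_per_point_usd",
]


def scorecards_to_frame(cards: list[ValueScorecard]) -> pd.DataFrame:
    """One machine-readable row per scorecard (separator-free numbers)."""
    rows = []
    for c in cards:
        rows.append(
            {
                "trial_name": c.trial_name,
                "regimen_name": c.regimen_name,
                "clinical_benefit": c.nhb.clinical_benefit,
                "toxicity_score": c.nhb.toxicity_score,
                "bonus_total": c.nhb.bonus.total,
                "nhb": c.nhb.nhb,
                "monthly_cost_cop": c.monthly_cost,
                "monthly_cost_usd": c.monthly_cost_usd,
                "cost_per_point_cop": c.cost_per_point,
                "cost_per_point_usd": c.cost_per_point_usd,
            }
        )
    return pd.DataFrame(rows, columns=SCORECARD_COLUMNS)


def comparison_frame(card_a: ValueScorecard, card_b: ValueScorecard) -> pd.DataFrame:
    """Side-by-side component table with a difference column (a minus b)."""
    rows = []
    for label, attr in [
        ("clinical_benefit", lambda c: c.nhb.clinical_benefit),
        ("toxicity_score", lambda c: c.nhb.toxicity_score),
        ("bonus_total", lambda c: c.nhb.bonus.total),
        ("nhb", lambda c: c.nhb.nhb),
        ("monthly_cost_cop", lambda c: c.monthly_cost),
        ("cost_per_point_cop", lambda c: c.cost_per_point),
    ]:
        a, b = attr(card_a), attr(card_b)
        rows.append({"component": label, card_a.trial_name: a, card_b.trial_name: b, "difference": a - b})
    return pd.DataFrame(rows)


def render_comparison(card_a: ValueScorecard, card_b: ValueScorecard) -> str:
    df = comparison_frame(card_a, card_b)
    header = f"# Comparison — {card_a.trial_name} ({card_a.regimen_name}) vs {card_b.trial_name} ({card_b.regimen_name})"
    cols = list(df.columns)
    lines = [header, "", "| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in df.iterrows():
        cells = [str(row[cols[0]])] + [_num(float(row[c])) for c in cols[1:]]
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    return "\n".join(lines)


def render_uncertainty(summary, label: Optional[str] = None) -> str:
    """Markdown block for a Monte-Carlo interval summary."""
    lines = [f"## Uncertainty ({summary.n_draws} draws, seed {summary.seed})"]
    if label:
        lines[0] += f" — {label}"
    lines.append("")
    lines.append("| quantile | NHB | cost per point (COP) |")
    lines.append("|---|---|---|")
    for p in sorted(summary.nhb_quantiles):
        cpp = summary.cost_per_point_quantiles.get(p, float("nan"))
        lines.append(f"| {p:g} | {summary.nhb_quantiles[p]:.2f} | {cpp:,.0f} |")
    lines.append("")
    return "\n".join(lines)
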