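"""Human-readable rendering of a StatReport as markdown tables."""

from __future__ import annotations

__all__ = ["render_markdown"]

_REGION_LABEL = {
    "total": "Total cerebral",
    "stimulated": "Stimulated hemisphere",
    "non_stimulated": "Non-stimulated hemisphere",
}


def _fmt(v, digits=3):
    if v is None:
        return ""
    return f"{v:.{digits}f}"


def render_markdown(report: dict) -> str:
    """Markdown summary of the blocks produced by ``run_full_analysis``
    (accepts the ``StatReport.to_dict()`` form)."""
    lines: list[str] = []
    meta = report.get("meta", {})
    lines.append("# Cohort analysis report")
    lines.append("")
    lines.append(
        f"n = {meta.get('n_hf', '?')} (HF) / {meta.get('n_lf', '?')} (LF); "
        f"correlation scope: {meta.get('correlation_scope', '?')}"
    )

    lines += ["", "## Baseline contrasts (HF vs LF)", "",
              "| variable | test | statistic | p |", "|---|---|---|---|"]
    for var, res in report["table1"].items():
        lines.append(
            f"| {var} | {res['name']} | {_fmt(res['statistic'], 2)} | "
            f"{_fmt(res['p_raw'])} |"
        )

    lines += ["", "## ALPS index group contrasts with adjusted regression", "",
              "| region | time | t | p | beta | 95% CI | p (adj.) |",
              "|---|---|---|---|---|---|---|"]
    for region, block in report["table2"].items():
        for tp, entry in block.items():
            t, reg = entry["t"], entry["regression"]
            lines.append(
                f"| {_REGION_LABEL[region]} | {tp.upper()} | "
                f"{_fmt(t['statistic'], 2)} | {_fmt(t['p_raw'])} | "
                f"{_fmt(reg['beta'])} | ({_fmt(reg['ci_low'])}, "
                f"{_fmt(reg['ci_high'])}) | {_fmt(reg['p_raw'])} |"
            )

    lines += ["", "## Longitudinal paired tests (BL - FU)", "",
              "| group | region | t | df | p |", "|---|---|---|---|---|"]
    for grp, block in report["longitudinal"].items():
        for region, res in block.items():
            lines.append(
                f"| {grp} | {_REGION_LABEL[region]} | "
                f"{_fmt(res['statistic'], 2)} | {_fmt(res['df'], 0)} | "
                f"{_fmt(res['p_raw'])} |"
            )

    lines += ["", "## Change-rate contrasts (HF - LF, % per day)", "",
              "| region | t | p | p (FDR) |", "|---|---|---|---|"]
    for region, res in report["table3"].items():
        lines.append(
            f"| {_REGION_LABEL[region]} | {_fmt(res['statistic'], 2)} | "
            f"{_fmt(res['p_raw'])} | {_fmt(res['p_fdr'])} |"
        )

    for label, title in (("baseline", "Baseline ALPS vs baseline scales"),
                         ("delta", "ALPS change rate vs scale change")):
        lines += ["", f"## Spearman correlations: {title}", ""]
        scales = list(next(iter(report["correlations"][label].values())))
        lines.append("| region | " + " | ".join(scales) + " |")
        lines.append("|" + "---|" * (len(scales) + 1))
        for region, row in report["correlations"][label].items():
            cells = " | ".join(_fmt(row[s]["statistic"], 2) for s in scales)
            lines.append(f"| {_REGION_LABEL[region]} | {cells} |")

    lines += ["", "FDR families (member counts): " + ", ".join(
        f"{k}={v}" for k, v in report["fdr_families"].items()), ""]
    return "\n".join(lines)
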