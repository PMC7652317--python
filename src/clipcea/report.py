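"""Human-readable and machine-readable result summaries."""

from __future__ import annotations

import json

from .engine import ArmOutcome, CEResult

__all__ = ["results_dict", "format_report", "write_results_json"]


def results_dict(result: CEResult, intervention: ArmOutcome, control: ArmOutcome,
                 label: str = "") -> dict:
    """Flatten a two-arm comparison into a JSON-serialisable mapping."""

    def arm(out: ArmOutcome) -> dict:
        return {
            "ly_discounted": out.ly,
            "qaly_discounted": out.qaly,
            "cost_discounted": out.cost,
            "ly_undiscounted": out.ly_undisc,
            "qaly_undiscounted": out.qaly_undisc,
            "cost_undiscounted": out.cost_undisc,
            "cost_upfront": out.cost_upfront,
            "cost_routine_discounted": out.cost_routine,
            "cost_hospitalisations_discounted": out.cost_hosp,
            "hospitalisations_lifetime_cohort": out.hosp_lifetime_cohort,
            "hospitalisations_24m_cohort": out.hosp_24m_cohort,
        }

    return {
        "label": label,
        "arms": {"PR+GDMT": arm(intervention), "GDMT": arm(control)},
        "incremental": {
            "delta_cost_discounted": result.delta_cost,
            "delta_qaly_discounted": result.delta_qaly,
            "delta_ly_discounted": result.delta_ly,
            "delta_cost_undiscounted": result.delta_cost_undisc,
            "delta_qaly_undiscounted": result.delta_qaly_undisc,
            "delta_ly_undiscounted": result.delta_ly_undisc,
            "icer_discounted": result.icer,
            "icer_undiscounted": result.icer_undisc,
            "status": result.status,
        },
    }


def _fmt(x, unit=""):
    if x is None:
        return "-"
    if unit == "eur":
        return f"€{x:,.2f}"
    return f"{x:.4f}"


def format_report(results: dict) -> str:
    """Render a results mapping as the text table mirroring the published layout."""
    lines = []
    label = results.get("label", "")
    lines.append(f"Cost-effectiveness results{f' ({label})' if label else ''}")
    lines.append("=" * 60)
    for arm_name, arm in results["arms"].items():
        lines.append(f"\n{arm_name}")
        lines.append("-" * len(arm_name))
        lines.append(
            f"  Life expectancy   : {arm['ly_discounted']:.4f} LY discounted, "
            f"{arm['ly_undiscounted']:.4f} LY undiscounted"
        )
        lines.append(
            f"  QALYs             : {arm['qaly_discounted']:.4f} discounted, "
            f"{arm['qaly_undiscounted']:.4f} undiscounted"
        )
        lines.append(
            f"  Costs             : {_fmt(arm['cost_discounted'], 'eur')} discounted, "
            f"{_fmt(arm['cost_undiscounted'], 'eur')} undiscounted"
        )
        lines.append(
            f"  Hospitalisations  : {arm['hospitalisations_24m_cohort']:.1f} within 24 m, "
            f"{arm['hospitalisations_lifetime_cohort']:.1f} lifetime (cohort)"
        )
    inc = results["incremental"]
    lines.append("\nIncremental (PR+GDMT minus GDMT)")
    lines.append("-" * 32)
    lines.append(f"  delta cost        : {_fmt(inc['delta_cost_discounted'], 'eur')} discounted")
    lines.append(f"  delta QALY        : {inc['delta_qaly_discounted']:.5f} discounted")
    lines.append(f"  delta LY          : {inc['delta_ly_discounted']:.5f} discounted")
    if inc["icer_discounted"] is not None:
        lines.append(f"  ICER              : {_fmt(inc['icer_discounted'], 'eur')} / QALY discounted")
    if inc["icer_undiscounted"] is not None:
        lines.append(f"  ICER (undisc.)    : {_fmt(inc['icer_undiscounted'], 'eur')} / QALY")
    lines.append(f"  status            : {inc['status']}")
    return "\n".join(lines)


def write_results_json(results: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2)
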