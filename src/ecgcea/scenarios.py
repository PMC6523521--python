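"""Scenario grid, ICER/dominance classification, and report writing.

The shipped scenario grid varies the assumptions a facility might
reasonably dispute - the 90-day SSI rate, the DSWI share, the
prolonged-ventilation share, the cohort (age/diabetes), and the lead
prices - and reruns the full 40-year model for each.  A strategy that is
cheaper and more effective than its comparator is *dominant* (no ICER is
computed); one that is costlier and less effective is *dominated*;
otherwise the incremental cost-effectiveness ratio is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .markov import run_base_case
from .params import ParameterError, ParameterSet

__all__ = [
    "ScenarioSpec",
    "ICERResult",
    "icer",
    "TABLE_SCENARIOS",
    "run_scenarios",
    "write_report",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter overrides."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of spECG vs rECG.

    ``delta_cost`` and ``delta_qaly`` are spECG minus rECG.
    """

    delta_cost: float
    delta_qaly: float
    classification: str
    icer: float | None = None

    def __str__(self) -> str:
        if self.icer is not None:
            return f"{self.icer:,.0f} $/QALY"
        return self.classification


def icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    """Classify an incremental (cost, QALY) pair.

    Dominant iff cheaper and more effective; Dominated iff costlier and
    less effective; a ratio is reported only when the signs agree and the
    QALY difference is non-zero.
    """
    if delta_qaly > 0 and delta_cost < 0:
        return ICERResult(delta_cost, delta_qaly, "Dominant")
    if delta_qaly < 0 and delta_cost > 0:
        return ICERResult(delta_cost, delta_qaly, "Dominated")
    if delta_qaly == 0:
        label = ("Cost-equal" if delta_cost == 0
                 else "Cost-only comparison (no QALY difference)")
        return ICERResult(delta_cost, delta_qaly, label)
    value = delta_cost / delta_qaly
    return ICERResult(delta_cost, delta_qaly, "ICER", value)


#: The shipped scenario grid (base case first).
TABLE_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("Base case"),
    ScenarioSpec("SSI rate: 2.5% after 90 days", {"ssi_rate_90d": 0.025}),
    ScenarioSpec("DSWI accounts for 0% of SSIs", {"dswi_share_of_ssi": 0.0}),
    ScenarioSpec("SSI: 2.5% and no DSWI",
                 {"ssi_rate_90d": 0.025, "dswi_share_of_ssi": 0.0}),
    ScenarioSpec("2% of CABG patients require pMV", {"pmv_share": 0.02}),
    ScenarioSpec("Population: age 60 and 10% diabetes",
                 {"age_years": 60.0, "diabetes_share": 0.10}),
    ScenarioSpec("rECG at $4 per use", {"recg_cost": 4.0}),
    ScenarioSpec("spECG at $30 per use", {"specg_cost": 30.0}),
)


def run_scenarios(base: ParameterSet,
                  scenarios: tuple[ScenarioSpec, ...] | list[ScenarioSpec]
                  = TABLE_SCENARIOS,
                  horizon_years: float | None = None) -> pd.DataFrame:
    """One row per scenario: per-arm cost/QALYs and the ICER classification.

    Scenarios are independent (each starts from ``base``); an override
    failing validation aborts that scenario only and is reported in the
    ``error`` column.
    """
    rows = []
    for sc in scenarios:
        row: dict = {"scenario": sc.name}
        try:
            p = base.replace(**sc.overrides)
            res = run_base_case(p, horizon_years)
            cls = icer(-res["delta_cost"], res["delta_qaly"])
            row.update({
                "recg_cost": res["rECG"].cost,
                "recg_qaly": res["rECG"].qalys,
                "specg_cost": res["spECG"].cost,
                "specg_qaly": res["spECG"].qalys,
                "delta_cost_specg": -res["delta_cost"],
                "delta_qaly_specg": res["delta_qaly"],
                "icer": str(cls),
                "error": "",
            })
        except (ParameterError, ValueError, RuntimeError) as exc:
            row.update({"recg_cost": float("nan"), "recg_qaly": float("nan"),
                        "specg_cost": float("nan"), "specg_qaly": float("nan"),
                        "delta_cost_specg": float("nan"),
                        "delta_qaly_specg": float("nan"),
                        "icer": "", "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows)


def _text_report(results: pd.DataFrame) -> str:
    lines = [
        f"{'Scenario':<38} {'rECG cost':>10} {'rECG QALY':>10} "
        f"{'spECG cost':>10} {'spECG QALY':>10}  ICER for spECG vs. rECG",
    ]
    for _, r in results.iterrows():
        if r.get("error"):
            lines.append(f"{r['scenario']:<38} failed: {r['error']}")
            continue
        lines.append(
            f"{r['scenario']:<38} {r['recg_cost']:>10,.0f} {r['recg_qaly']:>10.3f} "
            f"{r['specg_cost']:>10,.0f} {r['specg_qaly']:>10.3f}  {r['icer']}"
        )
    return "\n".join(lines) + "\n"


def write_report(results: pd.DataFrame, fmt: str, path: str | Path) -> Path:
    """Write a scenario-results table as CSV, JSON, or aligned text.

    Output is deterministic for identical inputs; currency is rounded to
    whole dollars and QALYs to three decimals in the text rendering.
    """
    path = Path(path)
    if fmt == "csv":
        results.to_csv(path, index=False, float_format="%.6f")
    elif fmt == "json":
        payload = results.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "text":
        path.write_text(_text_report(results))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path
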