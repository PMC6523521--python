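"""Epidemiological statistics for device-switch claims tables.

Works on 2x2 tables of surgical-site-infection (SSI) events by ECG lead
system (spECG = single-patient-use, exposed arm; rECG = reusable,
control arm), optionally stratified by facility or follow-up window.
Crude odds-ratio / relative-risk inference and the Mantel-Haenszel
pooled odds ratio are delegated to statsmodels; the odds<->probability
transform and the two-proportion sample-size formula are closed forms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable, Table2x2

__all__ = [
    "TwoByTwoTable",
    "StratifiedTables",
    "proportion",
    "percent_reduction",
    "odds_ratio",
    "relative_risk",
    "mantel_haenszel_or",
    "chi_square_p",
    "apply_or",
    "sample_size_two_proportions",
    "tables_from_claims",
    "analyze_claims",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Events / totals by arm.  Exposed = spECG, control = rECG."""

    exposed_events: int
    exposed_total: int
    control_events: int
    control_total: int
    label: str = ""

    def __post_init__(self) -> None:
        for events, total, arm in (
            (self.exposed_events, self.exposed_total, "exposed"),
            (self.control_events, self.control_total, "control"),
        ):
            if total <= 0:
                raise ValueError(f"{arm} arm has no observations")
            if not 0 <= events <= total:
                raise ValueError(f"{arm} arm: events {events} outside [0, {total}]")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, b, c, d) = exposed events/non-events, control events/non-events."""
        a = self.exposed_events
        b = self.exposed_total - self.exposed_events
        c = self.control_events
        d = self.control_total - self.control_events
        return a, b, c, d

    @property
    def degenerate(self) -> bool:
        """True when an event margin is empty (all events or none)."""
        a, b, c, d = self.cells
        return (a + c == 0) or (b + d == 0)

    def as_array(self, correction: bool = False) -> np.ndarray:
        arr = np.array(self.cells, dtype=float).reshape(2, 2)
        if correction:
            arr += 0.5
        return arr


@dataclass(frozen=True)
class StratifiedTables:
    """Ordered strata (per facility or time window) of 2x2 tables."""

    strata: tuple[TwoByTwoTable, ...]

    def __init__(self, strata: Iterable[TwoByTwoTable]):
        object.__setattr__(self, "strata", tuple(strata))
        if not self.strata:
            raise ValueError("at least one stratum is required")

    @property
    def informative(self) -> tuple[TwoByTwoTable, ...]:
        return tuple(t for t in self.strata if not t.degenerate)

    def crude(self, label: str = "pooled") -> TwoByTwoTable:
        """Cell-wise sum across strata."""
        return TwoByTwoTable(
            sum(t.exposed_events for t in self.strata),
            sum(t.exposed_total for t in self.strata),
            sum(t.control_events for t in self.strata),
            sum(t.control_total for t in self.strata),
            label,
        )


def proportion(events: int, total: int) -> float:
    """Event rate ``events / total``."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= events <= total:
        raise ValueError(f"events {events} outside [0, {total}]")
    return events / total


def percent_reduction(control_rate: float, exposed_rate: float) -> float:
    """Relative rate reduction, in percent: ``100 * (1 - exposed/control)``."""
    if control_rate <= 0:
        raise ValueError("control rate must be positive")
    return 100.0 * (1.0 - exposed_rate / control_rate)


def round_percent(rate: float, decimals: int = 1) -> float:
    """Half-up rounding of a rate to a one-decimal percentage (table style)."""
    scale = 10 ** decimals
    return math.floor(rate * 100 * scale + 0.5) / scale


def _maybe_correct(t: TwoByTwoTable) -> np.ndarray:
    a, b, c, d = t.cells
    if min(a, b, c, d) == 0:
        warnings.warn(
            f"zero cell in table {t.label!r}; applying 0.5 continuity correction",
            stacklevel=3,
        )
        return t.as_array(correction=True)
    return t.as_array()


def odds_ratio(t: TwoByTwoTable, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Crude odds ratio with Woolf (log-scale normal) confidence interval.

    A 0.5-cell continuity correction is applied, with a warning, when any
    interior cell is zero.
    """
    tab = Table2x2(_maybe_correct(t))
    return float(tab.oddsratio), tuple(map(float, tab.oddsratio_confint(alpha)))


def relative_risk(t: TwoByTwoTable, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Crude risk ratio (exposed vs control) with log-scale CI."""
    tab = Table2x2(_maybe_correct(t))
    return float(tab.riskratio), tuple(map(float, tab.riskratio_confint(alpha)))


def mantel_haenszel_or(s: StratifiedTables, alpha: float = 0.05
                       ) -> tuple[float, tuple[float, float]]:
    """Mantel-Haenszel pooled odds ratio across strata.

    The CI uses the Robins-Breslow-Greenland variance.  Strata with an
    empty event margin carry no information and are dropped.
    """
    usable = s.informative
    if not usable:
        raise ValueError("all strata are degenerate (empty event margin)")
    arrays = [t.as_array() for t in usable]
    st = StratifiedTable(arrays)
    return (float(st.oddsratio_pooled),
            tuple(map(float, st.oddsratio_pooled_confint(alpha))))


def chi_square_p(t: TwoByTwoTable, correction: bool = False) -> float:
    """Two-sided Pearson chi-square p-value (1 df) for a 2x2 table.

    Continuity (Yates) correction is off by default; the cells of the
    switch-cohort tables are large.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    res = sps.chi2_contingency(arr, correction=correction)
    return float(res.pvalue)


def apply_or(p: float, or_value: float) -> float:
    """Transform a probability through an odds ratio.

    ``odds' = odds * OR``; returns ``odds' / (1 + odds')``.
    """
    if not 0 <= p < 1:
        raise ValueError("p must lie in [0, 1)")
    if or_value < 0:
        raise ValueError("odds ratio must be non-negative")
    odds = p / (1.0 - p) * or_value
    return odds / (1.0 + odds)


def sample_size_two_proportions(
    p1: float,
    relative_reduction: float,
    alpha: float = 0.05,
    power: float = 0.80,
    sidedness: Literal["one", "two"] = "one",
) -> int:
    """Total N (both groups, equal allocation) to detect a relative reduction.

    Standard normal-approximation formula
    ``n/group = (z_a + z_b)^2 (p1 q1 + p2 q2) / (p1 - p2)^2`` with
    ``p2 = p1 (1 - relative_reduction)``; the total is ``2 * ceil(n/group)``.
    """
    if not 0 < p1 < 1:
        raise ValueError("p1 must lie in (0, 1)")
    if not 0 < relative_reduction < 1:
        raise ValueError("relative reduction must lie in (0, 1)")
    p2 = p1 * (1.0 - relative_reduction)
    z_a = sps.norm.ppf(1 - alpha / (2 if sidedness == "two" else 1))
    z_b = sps.norm.ppf(power)
    n_group = (z_a + z_b) ** 2 * (p1 * (1 - p1) + p2 * (1 - p2)) / (p1 - p2) ** 2
    return 2 * math.ceil(n_group)


# ---------------------------------------------------------------------------
# Claims-table I/O


_WINDOW_COLS = {"index": "ssi_index", "30": "ssi_30d", "90": "ssi_90d"}


def tables_from_claims(
    claims: pd.DataFrame,
    window: str = "90",
    stratify: Literal["none", "facility"] = "none",
) -> TwoByTwoTable | StratifiedTables:
    """Summarize per-procedure claims rows into 2x2 tables.

    ``claims`` needs columns ``facility_id, device, ssi_index, ssi_30d,
    ssi_90d`` with ``device`` in {"rECG", "spECG"}.
    """
    col = _WINDOW_COLS.get(str(window))
    if col is None:
        raise ValueError(f"unknown window {window!r}; expected one of "
                         f"{sorted(_WINDOW_COLS)}")
    if claims.empty:
        raise ValueError("claims table is empty")

    def _one(df: pd.DataFrame, label: str) -> TwoByTwoTable:
        sp = df[df["device"] == "spECG"]
        re = df[df["device"] == "rECG"]
        return TwoByTwoTable(
            int(sp[col].sum()), len(sp), int(re[col].sum()), len(re), label,
        )

    if stratify == "none":
        return _one(claims, f"{window} days")
    if stratify != "facility":
        raise ValueError("stratify must be 'none' or 'facility'")
    strata = [
        _one(group, str(fac))
        for fac, group in claims.groupby("facility_id", sort=True)
        if (group["device"] == "spECG").any() and (group["device"] == "rECG").any()
    ]
    return StratifiedTables(strata)


def analyze_claims(claims: pd.DataFrame, window: str = "90",
                   stratify: str = "none") -> dict:
    """Full summary used by the CLI: counts, rates, OR/RR, MH-OR, p-value."""
    crude = tables_from_claims(claims, window, "none")
    or_, or_ci = odds_ratio(crude)
    rr, rr_ci = relative_risk(crude)
    out = {
        "window": window,
        "control": {"events": crude.control_events, "total": crude.control_total,
                    "rate_pct": round_percent(proportion(crude.control_events,
                                                         crude.control_total))},
        "exposed": {"events": crude.exposed_events, "total": crude.exposed_total,
                    "rate_pct": round_percent(proportion(crude.exposed_events,
                                                         crude.exposed_total))},
        "percent_reduction": percent_reduction(
            proportion(crude.control_events, crude.control_total),
            proportion(crude.exposed_events, crude.exposed_total))
        if crude.control_events else None,
        "odds_ratio": {"estimate": or_, "ci95": list(or_ci)},
        "relative_risk": {"estimate": rr, "ci95": list(rr_ci)},
        "chi_square_p": chi_square_p(crude) if not crude.degenerate else None,
    }
    if stratify == "facility":
        strat = tables_from_claims(claims, window, "facility")
        mh, mh_ci = mantel_haenszel_or(strat)
        out["mantel_haenszel_or"] = {"estimate": mh, "ci95": list(mh_ci),
                                     "n_strata": len(strat.strata)}
    return out
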