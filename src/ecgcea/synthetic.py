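"""Synthetic claims-like CABG cohorts with known ground truth.

Emulates the switch-cohort extract the claims statistics operate on: 18
facilities that moved from reusable (rECG) to single-patient-use (spECG)
ECG leads, one row per CABG procedure with cumulative SSI indicator flags
at index admission / 30 days / 90 days.  Infection risk follows a
logistic model with a facility-level random intercept and a device odds
ratio, so the Mantel-Haenszel estimator can be validated against a known
truth without access to Medicare data.

Defaults reproduce the study conditions: expected arm totals of 2,167
rECG and 3,235 spECG procedures across 18 facilities, a 5.49% marginal
90-day SSI rate under rECG, a device odds ratio of 0.74, and the
index : 30-day : 90-day onset split 1.8 : 2.1 : 1.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = ["GeneratorConfig", "generate_cohort", "summarize_to_tables"]

from .claims import StratifiedTables, TwoByTwoTable, tables_from_claims

#: Arm totals observed in the 18-facility switch cohort.
_RECG_TOTAL, _SPECG_TOTAL = 2167, 3235


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth configuration for a synthetic switch cohort."""

    n_facilities: int = 18
    #: expected procedures per facility in each era (rECG, spECG); Poisson.
    cases_per_facility_per_era: tuple[float, float] = (
        _RECG_TOTAL / 18, _SPECG_TOTAL / 18)
    baseline_90d_rate: float = 0.0549
    true_or: float = 0.74
    #: fractions of SSIs with onset (index admission, by day 30, by day 90)
    onset_split: tuple[float, float, float] = (1.8 / 5.6, 2.1 / 5.6, 1.7 / 5.6)
    #: SD of facility-level log-odds intercepts
    facility_heterogeneity: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_facilities < 1:
            raise ValueError("need at least one facility")
        if not 0 < self.baseline_90d_rate < 1:
            raise ValueError("baseline rate must lie in (0, 1)")
        if self.true_or <= 0:
            raise ValueError("odds ratio must be positive")
        if abs(sum(self.onset_split) - 1.0) > 1e-12:
            raise ValueError("onset split must sum to 1")
        if min(self.onset_split) < 0:
            raise ValueError("onset split fractions must be non-negative")
        if self.facility_heterogeneity < 0:
            raise ValueError("facility heterogeneity must be non-negative")


def _centered_intercept(p0: float, sigma: float) -> float:
    """Intercept c such that E[expit(c + sigma Z)] = p0 for Z ~ N(0,1).

    Gauss-Hermite quadrature plus root finding; with sigma = 0 this is
    just logit(p0).
    """
    if sigma == 0:
        return float(special.logit(p0))
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def marginal(c: float) -> float:
        return float(weights @ special.expit(c + sigma * nodes)) - p0

    lo = special.logit(p0) - 5 * sigma - 1
    hi = special.logit(p0) + 5 * sigma + 1
    return float(optimize.brentq(marginal, lo, hi, xtol=1e-12))


def generate_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw one synthetic switch cohort.

    Returns a DataFrame with columns ``patient_id, facility_id, device,
    ssi_index, ssi_30d, ssi_90d`` (integer 0/1 flags, cumulative).
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    c0 = _centered_intercept(cfg.baseline_90d_rate, cfg.facility_heterogeneity)
    intercepts = c0 + cfg.facility_heterogeneity * rng.standard_normal(cfg.n_facilities)

    frames = []
    mean_r, mean_sp = cfg.cases_per_facility_per_era
    for j in range(cfg.n_facilities):
        for device, mean_n in (("rECG", mean_r), ("spECG", mean_sp)):
            n = int(rng.poisson(mean_n))
            if n == 0:
                continue
            logit_p = intercepts[j] + (np.log(cfg.true_or) if device == "spECG" else 0.0)
            p = special.expit(logit_p)
            ssi90 = rng.random(n) < p
            onset = rng.choice(3, size=n, p=np.asarray(cfg.onset_split))
            ssi_index = ssi90 & (onset == 0)
            ssi_30 = ssi90 & (onset <= 1)
            frames.append(pd.DataFrame({
                "facility_id": f"F{j + 1:02d}",
                "device": device,
                "ssi_index": ssi_index.astype(int),
                "ssi_30d": ssi_30.astype(int),
                "ssi_90d": ssi90.astype(int),
            }))
    if not frames:
        raise ValueError("configuration generated an empty cohort")
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "patient_id", [f"P{i + 1:06d}" for i in range(len(out))])
    return out


def summarize_to_tables(records: pd.DataFrame, window: str = "90",
                        stratify: str = "none"
                        ) -> TwoByTwoTable | StratifiedTables:
    """Collapse generated (or real) claims rows to 2x2 tables.

    Thin alias of :func:`ecgcea.claims.tables_from_claims` so generator
    output and CSV extracts share one code path.
    """
    return tables_from_claims(records, window, stratify)
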