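"""Probabilistic sensitivity analysis (PSA).

Every non-fixed parameter is sampled independently by inverse-CDF on a
truncated distribution: normal for most parameters, log-normal for the
relative risks and the SSI odds ratio.  The truncation interval comes
from the parameter's variance encoding (an explicit range, or +/-1.96 SD
for single-spread entries) intersected with its hard bounds, so a uniform
draw of 0 maps to the lower bound and 1 to the upper bound.

One uniform per parameter per draw is consumed in the documented registry
order from a single seeded generator, making runs reproducible and
insensitive to evaluation order.  Each draw reruns both monitoring arms
with the same sampled parameter set (arm differences enter only through
the odds ratio, the alarm relative risks, and lead prices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .markov import run_base_case
from .params import ParameterSet, ParameterSpec, truncation_bounds

__all__ = [
    "sample_parameter",
    "run_psa",
    "PSAResult",
    "summarize",
    "program_scale",
    "ce_plane_export",
]


def _lognormal_sigma(spec: ParameterSpec, lo: float, hi: float) -> float:
    if spec.has_range and lo > 0:
        return (np.log(hi) - np.log(lo)) / (2 * 1.96)
    s = float(spec.variance)  # type: ignore[arg-type]
    if spec.value - 1.96 * s > 0:
        return (np.log(spec.value + 1.96 * s)
                - np.log(spec.value - 1.96 * s)) / (2 * 1.96)
    return s / spec.value  # delta-method fallback for wide spreads


def sample_parameter(spec: ParameterSpec, u):
    """Inverse-CDF sample of one parameter at uniform ``u`` in [0, 1].

    ``u`` may be a scalar or an array (mapped elementwise).
    """
    u_arr = np.asarray(u, dtype=float)
    scalar = u_arr.ndim == 0
    if np.any((u_arr < 0.0) | (u_arr > 1.0)):
        raise ValueError("u must lie in [0, 1]")
    if spec.family == "fixed":
        out = np.full_like(u_arr, spec.value)
        return float(out) if scalar else out
    lo, hi = truncation_bounds(spec)
    if spec.family == "normal":
        if spec.has_range:
            sd = (hi - lo) / (2 * 1.96) if hi > lo else 0.0
        else:
            sd = float(spec.variance)  # type: ignore[arg-type]
        if sd == 0.0:
            out = np.full_like(u_arr, spec.value)
            return float(out) if scalar else out
        dist = sps.norm(spec.value, sd)
    elif spec.family == "lognormal":
        lo = max(lo, 1e-12)
        sigma = _lognormal_sigma(spec, lo, hi)
        if sigma == 0.0:
            out = np.full_like(u_arr, spec.value)
            return float(out) if scalar else out
        # scipy lognorm: shape = sigma, scale = exp(mu) with mu = ln(value)
        dist = sps.lognorm(s=sigma, scale=spec.value)
    else:  # pragma: no cover - families validated upstream
        raise ValueError(f"invalid family {spec.family!r}")
    f_lo, f_hi = dist.cdf(lo), dist.cdf(hi)
    if f_hi <= f_lo:
        out = np.full_like(u_arr, np.clip(spec.value, lo, hi))
        return float(out) if scalar else out
    x = dist.ppf(f_lo + u_arr * (f_hi - f_lo))
    x = np.clip(x, lo, hi)
    return float(x) if scalar else x


@dataclass
class PSAResult:
    """Per-draw incremental results and the seed that produced them.

    ``delta_cost`` is rECG cost minus spECG cost (positive = saving with
    single-patient-use leads); ``delta_qaly`` is spECG minus rECG.
    """

    draws: pd.DataFrame       # columns: draw, delta_cost, delta_qaly
    seed: int
    n_draws: int
    sampled_names: list[str]
    n_resampled: int = 0

    def summary(self) -> dict:
        return summarize(self)


def run_psa(params: ParameterSet, n_draws: int | None = None,
            seed: int = 0, horizon_years: float | None = None,
            max_retries: int = 10) -> PSAResult:
    """Run the seeded PSA: sample, rerun both arms, collect increments.

    Draws that produce an invalid model (out-of-range derived
    probabilities) are resampled with fresh uniforms, up to
    ``max_retries`` per draw.
    """
    if n_draws is None:
        n_draws = int(params["psa_draws"])
    if n_draws < 1:
        raise ValueError("need at least one draw")
    names = params.sampled_names()
    specs = [params.spec(n) for n in names]
    rng = np.random.default_rng(seed)
    u_matrix = rng.random((n_draws, len(names)))
    # inverse-CDF transform, vectorized per parameter across draws
    if specs:
        value_matrix = np.column_stack(
            [sample_parameter(s, u_matrix[:, j]) for j, s in enumerate(specs)])
    else:
        value_matrix = np.zeros((n_draws, 0))

    rows = []
    n_resampled = 0
    for i in range(n_draws):
        values = dict(zip(names, value_matrix[i]))
        for attempt in range(max_retries + 1):
            try:
                drawn = params.replace(**values)
                res = run_base_case(drawn, horizon_years)
                break
            except (ValueError, RuntimeError):
                if attempt == max_retries:
                    raise RuntimeError(
                        f"draw {i}: no valid parameter sample after "
                        f"{max_retries} retries")
                n_resampled += 1
                u = rng.random(len(names))
                values = {n: sample_parameter(s, ui)
                          for n, s, ui in zip(names, specs, u)}
        rows.append((i, res["delta_cost"], res["delta_qaly"]))
    draws = pd.DataFrame(rows, columns=["draw", "delta_cost", "delta_qaly"])
    return PSAResult(draws=draws, seed=seed, n_draws=n_draws,
                     sampled_names=names, n_resampled=n_resampled)


def summarize(psa: PSAResult) -> dict:
    """Mean, median, and empirical 95% credible interval per outcome.

    The interval is a credible interval (the central 95% of simulation
    results), not a frequentist confidence interval; model results are
    not normally distributed.
    """
    if len(psa.draws) < 2:
        raise ValueError("need at least two draws to summarize")
    out: dict = {"n_draws": psa.n_draws, "seed": psa.seed,
                 "interval_type": "credible interval (CrI)"}
    for col in ("delta_cost", "delta_qaly"):
        x = psa.draws[col].to_numpy()
        lo, hi = np.percentile(x, [2.5, 97.5])
        out[col] = {
            "mean": float(np.mean(x)),
            "median": float(np.median(x)),
            "cri95": [float(lo), float(hi)],
        }
    dom = ((psa.draws["delta_cost"] > 0) & (psa.draws["delta_qaly"] > 0)).mean()
    out["dominance_fraction"] = float(dom)
    return out


def program_scale(per_patient: float, annual_procedures: float = 86000) -> float:
    """Annual program-level amount: per-patient value times yearly volume."""
    if per_patient < 0 or annual_procedures < 0:
        raise ValueError("inputs must be non-negative")
    return per_patient * annual_procedures


def format_millions(dollars: float) -> str:
    return f"${dollars / 1e6:.0f} million"


def ce_plane_export(psa: PSAResult, wtp: float = 25000.0
                    ) -> tuple[pd.DataFrame, dict]:
    """Cost-effectiveness plane data for plotting.

    X is the QALY change with spECG; Y is the *cost change* with spECG
    (the negative of the saving), so dominant draws fall in the
    south-east quadrant.  Returns the per-draw table and metadata with
    quadrant counts and the willingness-to-pay line specification.
    """
    if psa.draws.empty:
        raise ValueError("PSA has no draws")
    df = pd.DataFrame({
        "delta_qaly": psa.draws["delta_qaly"],
        "delta_cost_specg": -psa.draws["delta_cost"],
    })

    def quadrant(row) -> str:
        dq, dc = row["delta_qaly"], row["delta_cost_specg"]
        if dq == 0 and dc == 0:
            return "on_threshold"
        if dq > 0 and dc < 0:
            return "dominant"
        if dq < 0 and dc > 0:
            return "dominated"
        if dq >= 0:
            return "north_east" if dc >= 0 else "dominant"
        return "south_west"

    df["quadrant"] = df.apply(quadrant, axis=1)
    counts = df["quadrant"].value_counts().to_dict()
    meta = {
        "wtp_per_qaly": wtp,
        "wtp_line": {"slope": wtp, "intercept": 0.0,
                     "x": "delta_qaly", "y": "delta_cost_specg"},
        "quadrant_counts": counts,
        "n_draws": len(df),
    }
    return df, meta
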