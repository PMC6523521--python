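"""Model parameter registry: definitions, validation, loading, serialization.

Every quantity used anywhere in the cohort model, the probabilistic
sensitivity analysis (PSA), or the scenario grid is declared here exactly
once as a :class:`ParameterSpec`.  Each spec carries the base-case value,
an uncertainty encoding (either a single standard deviation or an explicit
(low, high) range), the sampling family used by the PSA, and hard
admissibility bounds (probabilities in [0, 1], durations >= 0, ...).

Percentage-valued parameters are stored as proportions; their
single-number spreads are standard deviations in percentage points
(converted here to the proportion scale).  Dollar- and day-valued spreads
are standard deviations on the natural scale.  Single-spread parameters
are truncated at +/-1.96 SD when sampled, so the truncation interval spans
a 95% range, mirroring range-encoded parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "ParameterError",
    "DEFAULT_SPECS",
    "load_parameters",
    "truncation_bounds",
    "schema",
]

_FAMILIES = ("normal", "lognormal", "fixed")

INF = math.inf


class ParameterError(ValueError):
    """Raised for malformed configurations or out-of-bounds values."""


@dataclass(frozen=True)
class ParameterSpec:
    """Definition of a single model parameter.

    Parameters
    ----------
    name : str
        Unique identifier (snake_case).
    value : float
        Base-case (deterministic) value.
    variance : float or (float, float)
        Either a single standard deviation or an explicit (low, high)
        range bounding the 95% uncertainty interval.
    family : {"normal", "lognormal", "fixed"}
        Sampling distribution for the PSA.  ``fixed`` parameters are
        never varied.
    units : str
        Free-text units, for reporting.
    hard_bounds : (float, float)
        Admissible interval; sampling is truncated to it and loaded
        values are validated against it.
    """

    name: str
    value: float
    variance: float | tuple[float, float]
    family: str
    units: str = ""
    hard_bounds: tuple[float, float] = (-INF, INF)
    description: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(
                f"{self.name}: unknown family {self.family!r}; expected one of {_FAMILIES}"
            )
        lo, hi = self.hard_bounds
        if not (lo <= self.value <= hi):
            raise ParameterError(
                f"{self.name}: value {self.value} outside hard bounds [{lo}, {hi}]"
            )
        if self.has_range:
            rlo, rhi = self.variance  # type: ignore[misc]
            if rlo > rhi:
                raise ParameterError(
                    f"{self.name}: range variance has low {rlo} > high {rhi}"
                )
            if not (rlo <= self.value <= rhi):
                raise ParameterError(
                    f"{self.name}: value {self.value} outside variance range ({rlo}, {rhi})"
                )
        if self.family == "lognormal" and self.value <= 0:
            raise ParameterError(
                f"{self.name}: lognormal family requires a strictly positive value"
            )

    @property
    def has_range(self) -> bool:
        return isinstance(self.variance, (tuple, list))

    def with_value(self, value: float) -> "ParameterSpec":
        """Copy of this spec at a different base value (variance untouched)."""
        variance = self.variance
        if self.has_range:
            rlo, rhi = variance  # type: ignore[misc]
            variance = (min(rlo, value), max(rhi, value))
        return ParameterSpec(
            self.name, value, variance, self.family, self.units,
            self.hard_bounds, self.description,
        )


def truncation_bounds(spec: ParameterSpec) -> tuple[float, float]:
    """Sampling truncation interval for *spec*.

    Range-encoded variances are intersected with the hard bounds; a single
    spread ``s`` yields ``value +/- 1.96 s`` intersected with the hard
    bounds; ``fixed`` parameters collapse to the degenerate point.
    """
    lo_h, hi_h = spec.hard_bounds
    if spec.family == "fixed":
        return (spec.value, spec.value)
    if spec.has_range:
        rlo, rhi = spec.variance  # type: ignore[misc]
    else:
        s = float(spec.variance)  # type: ignore[arg-type]
        rlo, rhi = spec.value - 1.96 * s, spec.value + 1.96 * s
    lo, hi = max(rlo, lo_h), min(rhi, hi_h)
    if lo > hi:
        raise ParameterError(
            f"{spec.name}: truncation interval empty after intersecting "
            f"({rlo}, {rhi}) with hard bounds ({lo_h}, {hi_h})"
        )
    if lo == hi and spec.family != "fixed":
        raise ParameterError(
            f"{spec.name}: degenerate truncation interval for non-fixed family"
        )
    return (lo, hi)


def _pct(x: float) -> float:
    """Percentage points -> proportion."""
    return x / 100.0


_P01 = (0.0, 1.0)


def _default_specs() -> dict[str, ParameterSpec]:
    """The built-in registry: base-case table values plus package defaults.

    Registry insertion order is the documented PSA sampling order.
    """
    specs = [
        # --- patient cohort -------------------------------------------------
        ParameterSpec("age_years", 73.0, 2.3, "normal", "years", (40.0, 100.0),
                      "Cohort age at CABG"),
        ParameterSpec("female_share", 0.298, _pct(0.18), "normal", "proportion", _P01),
        ParameterSpec("obese_share", 0.35, _pct(0.48), "normal", "proportion", _P01,
                      "Obese (non-morbid) share of cohort"),
        ParameterSpec("morbid_obese_share", 0.06, _pct(0.24), "normal", "proportion", _P01),
        ParameterSpec("diabetes_share", 0.452, _pct(0.19), "normal", "proportion", _P01),
        # --- clinical settings ----------------------------------------------
        ParameterSpec("mv_days", 0.5, 0.0001, "normal", "days", (0.0, 30.0),
                      "Routine post-operative mechanical-ventilation time"),
        ParameterSpec("icu_days", 1.0, 0.0001, "normal", "days", (0.0, 60.0),
                      "Routine ICU time after extubation"),
        ParameterSpec("hospital_days", 8.0, 1.79, "normal", "days", (0.0, 60.0),
                      "Routine index-admission length of stay"),
        ParameterSpec("pmv_share", 0.106, _pct(0.0001), "normal", "proportion", _P01,
                      "Share of patients requiring prolonged mechanical ventilation"),
        ParameterSpec("ecg_monitoring_days", 8.0, 1.79, "normal", "days", (0.0, 60.0)),
        ParameterSpec("home_discharge_share", 0.745, _pct(0.17), "normal", "proportion", _P01),
        ParameterSpec("inhospital_mortality", 0.027, _pct(0.067), "normal", "proportion", _P01,
                      "Cumulative in-hospital (index admission) mortality"),
        ParameterSpec("dswi_share_of_ssi", 0.4075, _pct(2.6), "normal", "proportion", _P01,
                      "Deep sternal wound infections as a share of all SSIs"),
        ParameterSpec("ssi_extra_los_days", 13.3, 20.8, "normal", "days", (0.0, 120.0),
                      "Additional inpatient days to treat a (non-DSWI) SSI"),
        ParameterSpec("dswi_extra_los_days", 24.0, 5.0, "normal", "days", (0.0, 120.0)),
        ParameterSpec("false_alarm_rate", 0.979, 0.0143, "normal",
                      "alarms per patient-day", (0.0, 10.0)),
        ParameterSpec("leadsoff_alarm_rate", 0.409, 0.0492, "normal",
                      "alarms per patient-day", (0.0, 10.0)),
        # --- relative effects (lognormal) -----------------------------------
        ParameterSpec("rr_false_alarm_specg", 0.81, 0.13, "lognormal", "RR", (1e-6, 10.0)),
        ParameterSpec("rr_leadsoff_specg", 0.71, 0.15, "lognormal", "RR", (1e-6, 10.0)),
        ParameterSpec("rr_dswi_morbid_obese", 6.45, 0.40, "lognormal", "RR", (1e-6, 50.0)),
        ParameterSpec("rr_mortality_morbid_obese", 1.64, 0.18, "lognormal", "RR", (1e-6, 50.0)),
        ParameterSpec("rr_dswi_diabetes", 1.71, 0.20, "lognormal", "RR", (1e-6, 50.0)),
        ParameterSpec("or_ssi_specg", 0.74, (0.62, 0.89), "lognormal", "odds ratio",
                      (1e-6, 10.0),
                      "Odds ratio for 90-day SSI with spECG vs rECG (claims-derived)"),
        # --- costs (2016 USD) -----------------------------------------------
        ParameterSpec("recg_cost", 9.08, 1.66, "normal", "$/use", (0.0, INF)),
        ParameterSpec("specg_cost", 15.0, 2.0, "normal", "$/use", (0.0, INF)),
        ParameterSpec("cabg_cost", 10244.0, 2664.0, "normal", "$", (0.0, INF)),
        ParameterSpec("mv_cost_day", 756.0, (210.0, 906.0), "normal", "$/day", (0.0, INF),
                      "Mechanical-ventilation per-diem, added to the ICU per-diem"),
        ParameterSpec("icu_cost_day", 2536.0, (2197.0, 3066.0), "normal", "$/day", (0.0, INF)),
        ParameterSpec("nurse_cost_hour", 58.0, 4.6, "normal", "$/hour", (0.0, INF)),
        ParameterSpec("ssi_inpatient_day_delta", -158.0, 210.0, "normal", "$/day",
                      (-5000.0, 5000.0),
                      "Per-day increment applied to the ward per-diem on SSI-care days "
                      "(SSIs lengthen stays but lower the mean daily cost)"),
        ParameterSpec("ssi_outpatient_cost", 2583.0, 838.0, "normal", "$", (0.0, INF),
                      "One-time outpatient care cost per non-DSWI outpatient SSI"),
        ParameterSpec("dswi_readmission_cost", 23586.0, 6815.0, "normal", "$", (0.0, INF),
                      "One-time admission payment for a DSWI readmission"),
        ParameterSpec("future_care_annual", 4673.1, 524.0, "normal", "$/year", (0.0, INF)),
        ParameterSpec("future_care_decrement", 92.29, 215.0, "normal", "$/year^2",
                      (-5000.0, 5000.0),
                      "Annual decline in the future-care cost rate per elapsed year"),
        # --- quality of life (EQ-5D utilities) ------------------------------
        ParameterSpec("u_baseline", 0.85, 0.158, "normal", "utility", (0.0, 1.0)),
        ParameterSpec("u_cabg", 0.741, 0.191, "normal", "utility", (0.0, 1.0),
                      "Utility at the point of CABG; start of the year-1 recovery ramp"),
        ParameterSpec("u_mv_decrement", -0.39, (-0.59, -0.09), "normal", "utility",
                      (-1.0, 0.0), "Decrement added to the ICU utility while ventilated"),
        ParameterSpec("u_icu", 0.402, (0.36, 0.44), "normal", "utility", (0.0, 1.0)),
        ParameterSpec("u_gw", 0.52, (0.45, 0.59), "normal", "utility", (0.0, 1.0)),
        ParameterSpec("u_ssi_decrement", 0.198, (0.04, 0.8), "normal", "utility", (0.0, 1.0),
                      "Utility decrement during active SSI care"),
        # --- epidemiology ----------------------------------------------------
        ParameterSpec("ssi_rate_90d", 0.0549, 0.0049, "normal", "proportion", _P01,
                      "Cumulative 90-day SSI incidence under rECG (2014 claims); "
                      "SD is the binomial SE at n = 2,167"),
        ParameterSpec("onset_index_share", 1.8 / 5.6, 0.0, "fixed", "proportion", _P01,
                      "Share of 90-day SSIs with onset during the index admission"),
        ParameterSpec("onset_30d_share", 2.1 / 5.6, 0.0, "fixed", "proportion", _P01,
                      "Share of 90-day SSIs with onset after discharge, by day 30"),
        # --- economics and engine defaults ----------------------------------
        ParameterSpec("discount_rate", 0.035, 0.0, "fixed", "per year", (0.0, 0.2),
                      "Annual discount rate applied after the first model year"),
        # Calibrated against the printed 1-year rECG total; see markov.calibrate_gw_daily_cost.
        ParameterSpec("gw_cost_day", 2589.03, 258.903, "normal", "$/day", (0.0, INF),
                      "Effective general-ward per-diem bundling all otherwise-unlisted "
                      "acute-care costs (calibrated; 10% SD package default)"),
        # Calibrated closed-form against the printed mean ICU stay of 2.3 days.
        ParameterSpec("pmv_extra_icu_days", 7.5472, 0.0, "fixed", "days", (0.0, 90.0),
                      "Extra ICU+MV days for the prolonged-MV branch (calibrated)"),
        ParameterSpec("nurse_min_per_alarm", 1.5, 0.0, "fixed", "minutes", (0.0, 60.0)),
        ParameterSpec("outpatient_ssi_episode_days", 21.0, 0.0, "fixed", "days", (0.0, 120.0)),
        ParameterSpec("care_home_extra_annual", 0.0, 0.0, "fixed", "$/year", (0.0, INF)),
        ParameterSpec("ssi_death_hazard_ratio", 2.0, 0.0, "fixed", "hazard ratio",
                      (1e-6, 20.0),
                      "In-hospital death-hazard ratio on SSI-care days"),
        ParameterSpec("bg_mortality_q0", 0.045, 0.0, "fixed", "per year", _P01,
                      "Annual background death probability at the reference age of 73"),
        ParameterSpec("bg_mortality_doubling_years", 8.5, 0.0, "fixed", "years",
                      (1.0, 50.0), "Gompertz mortality doubling time"),
        ParameterSpec("horizon_years", 40.0, 0.0, "fixed", "years", (1.0, 100.0)),
        ParameterSpec("psa_draws", 2000.0, 0.0, "fixed", "count", (1.0, INF)),
        ParameterSpec("annual_cabg_volume", 86000.0, 0.0, "fixed", "procedures/year",
                      (0.0, INF)),
        ParameterSpec("wtp_per_qaly", 25000.0, 0.0, "fixed", "$/QALY", (0.0, INF)),
    ]
    return {s.name: s for s in specs}


DEFAULT_SPECS: dict[str, ParameterSpec] = _default_specs()


@dataclass
class ParameterSet(Mapping):
    """An immutable-by-convention mapping of parameter name -> spec.

    Behaves as a ``Mapping[str, float]`` over base-case values; full
    specs are reachable through :attr:`specs`.
    """

    specs: dict[str, ParameterSpec] = field(default_factory=_default_specs)

    # Mapping protocol over values -------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.specs[name].value

    def __iter__(self) -> Iterator[str]:
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def spec(self, name: str) -> ParameterSpec:
        return self.specs[name]

    def sampled_names(self) -> list[str]:
        """Names of parameters the PSA varies, in documented order."""
        return [n for n, s in self.specs.items() if s.family != "fixed"]

    def replace(self, **values: float) -> "ParameterSet":
        """New set with the given base values overridden (validated)."""
        unknown = sorted(set(values) - set(self.specs))
        if unknown:
            raise ParameterError(f"unknown parameter(s): {', '.join(unknown)}")
        specs = dict(self.specs)
        for name, value in values.items():
            old = specs[name]
            lo, hi = old.hard_bounds
            if not (lo <= value <= hi):
                raise ParameterError(
                    f"{name}: value {value} outside hard bounds [{lo}, {hi}]"
                )
            specs[name] = old.with_value(float(value))
        return ParameterSet(specs)

    # Serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for name, s in self.specs.items():
            out[name] = {
                "value": s.value,
                "variance": list(s.variance) if s.has_range else s.variance,
                "family": s.family,
                "units": s.units,
            }
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def __eq__(self, other) -> bool:  # value-and-spec equality
        return isinstance(other, ParameterSet) and self.specs == other.specs


def _coerce_entry(name: str, base: ParameterSpec | None, entry) -> ParameterSpec:
    if isinstance(entry, (int, float)):
        entry = {"value": float(entry)}
    if not isinstance(entry, dict):
        raise ParameterError(f"{name}: entry must be a number or an object")
    if base is None and "value" not in entry:
        raise ParameterError(f"{name}: new parameter requires a 'value'")
    value = float(entry.get("value", base.value if base else 0.0))
    variance = entry.get("variance", base.variance if base else 0.0)
    if isinstance(variance, (list, tuple)):
        variance = (float(variance[0]), float(variance[1]))
    else:
        variance = float(variance)
    family = entry.get("family", base.family if base else "fixed")
    units = entry.get("units", base.units if base else "")
    bounds = base.hard_bounds if base else (-INF, INF)
    desc = base.description if base else ""
    return ParameterSpec(name, value, variance, family, units, bounds, desc)


def load_parameters(config_text: str | dict | None = None,
                    *, strict: bool = True) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a JSON document.

    ``config_text`` may be a JSON string, an already-parsed dict, or
    ``None``/empty (returning the built-in defaults).  Entries override
    the registry; each entry is either a bare number (overriding the
    value) or an object with any of ``value``, ``variance``, ``family``,
    ``units``.  Unknown keys are rejected with their names listed when
    ``strict`` (the default).
    """
    if config_text is None:
        return ParameterSet()
    if isinstance(config_text, str):
        if not config_text.strip():
            return ParameterSet()
        try:
            doc = json.loads(config_text)
        except json.JSONDecodeError as exc:
            raise ParameterError(f"could not parse parameter JSON: {exc}") from exc
    else:
        doc = config_text
    if not isinstance(doc, dict):
        raise ParameterError("parameter document must be a JSON object")
    defaults = _default_specs()
    unknown = sorted(set(doc) - set(defaults))
    if strict and unknown:
        raise ParameterError(f"unknown parameter(s): {', '.join(unknown)}")
    specs = dict(defaults)
    for name, entry in doc.items():
        base = defaults.get(name)
        spec = _coerce_entry(name, base, entry)
        lo, hi = spec.hard_bounds
        if not (lo <= spec.value <= hi):
            raise ParameterError(
                f"{name}: value {spec.value} outside hard bounds [{lo}, {hi}]"
            )
        specs[name] = spec
    pset = ParameterSet(specs)
    # sanity: every non-fixed parameter must have a usable truncation interval
    for s in pset.specs.values():
        if s.family != "fixed":
            truncation_bounds(s)
    return pset


def schema() -> dict:
    """Machine-readable description of every registered parameter."""
    return {
        name: {
            "value": s.value,
            "variance": list(s.variance) if s.has_range else s.variance,
            "family": s.family,
            "units": s.units,
            "hard_bounds": [s.hard_bounds[0], s.hard_bounds[1]],
            "description": s.description,
        }
        for name, s in DEFAULT_SPECS.items()
    }
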