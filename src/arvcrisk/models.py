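"""The ARVC 5-year ventricular-arrhythmia risk equation.

The model is a fixed proportional-hazards risk score with seven clinical
covariates.  For a patient with covariate vector x the linear predictor is

    LP = 0.488*sex - 0.022*age + 0.657*syncope + 0.811*nsvt
         + 0.170*ln(PVC) + 0.113*TWI - 0.025*RVEF

and the predicted probability of a sustained ventricular arrhythmia within
t years is ``1 - S0(t)**exp(LP)``, where ``S0`` is a tabulated baseline
survival (survival of a hypothetical patient with LP = 0).  Both the
originally published baseline table and a recalibrated variant (baseline
shifted on the log-hazard scale for a higher-risk, secondary-prevention
population) ship as packaged model specs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RiskModelSpec",
    "PatientCovariates",
    "MissingPVCError",
    "UnknownHorizonError",
    "linear_predictor",
    "cohort_linear_predictor",
    "predicted_risk",
    "risk_from_lp",
    "survival_from_lp",
    "predicted_survival_curve",
    "baseline_cumulative_hazard",
    "load_model",
    "published_model",
    "recalibrated_model",
]

#: horizon keys are matched within this absolute tolerance (floats from CSV/JSON)
_HORIZON_TOL = 1e-9


class MissingPVCError(ValueError):
    """Raised when a patient's 24-h PVC count is absent: imputation required."""


class UnknownHorizonError(LookupError):
    """Raised for a horizon not tabulated in the baseline-survival table."""


@dataclass(frozen=True)
class RiskModelSpec:
    """A proportional-hazards risk equation: coefficients + baseline survival.

    Coefficients are per-unit log-hazard ratios on the covariates' natural
    scales (age in years, RVEF in percent, PVC entering as its natural log,
    TWI as a lead count).  ``s0_table`` maps a horizon in years to the
    baseline survival probability S0(t), strictly inside (0, 1) and
    non-increasing in t.
    """

    coef_sex: float
    coef_age: float
    coef_syncope: float
    coef_nsvt: float
    coef_ln_pvc: float
    coef_twi: float
    coef_rvef: float
    s0_table: Mapping[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        for name, value in self.coefficients.items():
            if not math.isfinite(value):
                raise ValueError(f"coefficient {name!r} must be finite, got {value}")
        if not self.s0_table:
            raise ValueError("s0_table must be non-empty")
        table = {float(t): float(s) for t, s in self.s0_table.items()}
        horizons = sorted(table)
        if horizons[0] <= 0:
            raise ValueError("s0_table horizons must be positive")
        values = [table[t] for t in horizons]
        if any(not (0.0 < s < 1.0) for s in values):
            raise ValueError("s0_table values must lie strictly in (0, 1)")
        if any(b > a for a, b in zip(values, values[1:])):
            raise ValueError("s0_table must be non-increasing in horizon")
        object.__setattr__(self, "s0_table", table)

    @property
    def coefficients(self) -> dict[str, float]:
        return {
            "sex_male": self.coef_sex,
            "age_years": self.coef_age,
            "recent_syncope": self.coef_syncope,
            "nsvt_history": self.coef_nsvt,
            "ln_pvc": self.coef_ln_pvc,
            "twi_leads": self.coef_twi,
            "rvef_pct": self.coef_rvef,
        }

    @property
    def horizons(self) -> tuple[float, ...]:
        return tuple(sorted(self.s0_table))

    def baseline_survival(self, horizon: float) -> float:
        """S0 at a tabulated horizon; exact-key lookup, no interpolation."""
        for t, s in self.s0_table.items():
            if abs(t - float(horizon)) <= _HORIZON_TOL:
                return s
        raise UnknownHorizonError(
            f"horizon {horizon} not tabulated (available: {self.horizons})"
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "coefficients": self.coefficients,
            "s0_table": {str(t): s for t, s in sorted(self.s0_table.items())},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RiskModelSpec":
        c = payload["coefficients"]
        return cls(
            coef_sex=float(c["sex_male"]),
            coef_age=float(c["age_years"]),
            coef_syncope=float(c["recent_syncope"]),
            coef_nsvt=float(c["nsvt_history"]),
            coef_ln_pvc=float(c["ln_pvc"]),
            coef_twi=float(c["twi_leads"]),
            coef_rvef=float(c["rvef_pct"]),
            s0_table={float(t): float(s) for t, s in payload["s0_table"].items()},
            label=str(payload.get("label", "")),
        )

    @classmethod
    def from_json(cls, path) -> "RiskModelSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def with_s0_table(self, table: Mapping[float, float], label: str | None = None) -> "RiskModelSpec":
        return replace(self, s0_table=dict(table), label=self.label if label is None else label)


@dataclass(frozen=True)
class PatientCovariates:
    """One patient's predictors, in the units the equation expects.

    ``pvc_24h`` may be ``None`` (missing); the linear predictor then refuses
    to evaluate until median imputation has run.  ``twi_max`` caps the TWI
    lead count; the default of 7 corresponds to the anterior (V1–V4) plus
    inferior (II, III, aVF) leads, but the cap is configurable because the
    exact lead set is a reporting convention rather than part of the model.
    """

    sex_male: int
    age_years: float
    recent_syncope: int
    nsvt_history: int
    pvc_24h: float | None
    twi_leads: int
    rvef_pct: float
    twi_max: int = field(default=7, compare=False)

    def __post_init__(self) -> None:
        for name in ("sex_male", "recent_syncope", "nsvt_history"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if not 0 <= self.twi_leads <= self.twi_max:
            raise ValueError(f"twi_leads must lie in 0..{self.twi_max}")
        if not 0.0 <= self.rvef_pct <= 100.0:
            raise ValueError("rvef_pct must lie in [0, 100]")
        if self.pvc_24h is not None:
            if isinstance(self.pvc_24h, float) and math.isnan(self.pvc_24h):
                object.__setattr__(self, "pvc_24h", None)
            elif self.pvc_24h < 0:
                raise ValueError("pvc_24h must be non-negative")


def _ln_pvc(pvc) -> float:
    # count of 0 is floored to 1 before the log (ln 0 undefined)
    return math.log(max(float(pvc), 1.0))


def linear_predictor(model: RiskModelSpec, patient: PatientCovariates) -> float:
    """Weighted covariate sum LP for one patient.

    Raises :class:`MissingPVCError` if the PVC count is missing — the
    analysis pipeline imputes the cohort median before scoring.
    """
    if patient.pvc_24h is None:
        raise MissingPVCError("pvc_24h is missing: imputation required before scoring")
    return (
        model.coef_sex * patient.sex_male
        + model.coef_age * patient.age_years
        + model.coef_syncope * patient.recent_syncope
        + model.coef_nsvt * patient.nsvt_history
        + model.coef_ln_pvc * _ln_pvc(patient.pvc_24h)
        + model.coef_twi * patient.twi_leads
        + model.coef_rvef * patient.rvef_pct
    )


def cohort_linear_predictor(model: RiskModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    """Vectorised LP over a cohort table (columns per the cohort CSV schema)."""
    pvc = cohort["pvc_24h"].to_numpy(dtype=float)
    if np.isnan(pvc).any():
        raise MissingPVCError("cohort has missing pvc_24h values: run impute_pvc_median first")
    return (
        model.coef_sex * cohort["sex_male"].to_numpy(dtype=float)
        + model.coef_age * cohort["age_years"].to_numpy(dtype=float)
        + model.coef_syncope * cohort["recent_syncope"].to_numpy(dtype=float)
        + model.coef_nsvt * cohort["nsvt_history"].to_numpy(dtype=float)
        + model.coef_ln_pvc * np.log(np.maximum(pvc, 1.0))
        + model.coef_twi * cohort["twi_leads"].to_numpy(dtype=float)
        + model.coef_rvef * cohort["rvef_pct"].to_numpy(dtype=float)
    )


def survival_from_lp(model: RiskModelSpec, lp, horizon: float):
    """S0(horizon) ** exp(LP); accepts a scalar or an array of LPs."""
    s0 = model.baseline_survival(horizon)
    return s0 ** np.exp(lp)


def risk_from_lp(model: RiskModelSpec, lp, horizon: float):
    """1 - S0(horizon) ** exp(LP); accepts a scalar or an array of LPs."""
    return 1.0 - survival_from_lp(model, lp, horizon)


def predicted_risk(model: RiskModelSpec, patient: PatientCovariates, horizon: float) -> float:
    """Predicted probability of the event within ``horizon`` years."""
    return float(risk_from_lp(model, linear_predictor(model, patient), horizon))


def predicted_survival_curve(model: RiskModelSpec, patient: PatientCovariates) -> dict[float, float]:
    """Patient-specific survival S0(t)**exp(LP) at every tabulated horizon."""
    lp = linear_predictor(model, patient)
    return {t: float(survival_from_lp(model, lp, t)) for t in model.horizons}


def baseline_cumulative_hazard(model: RiskModelSpec, times) -> np.ndarray:
    """Baseline cumulative hazard H0(t) = -ln S0(t), interpolated.

    The hazard is taken piecewise-constant between the tabulated horizons
    (so H0 is piecewise linear, starting from H0(0) = 0) with flat
    extrapolation of the last interval's hazard rate beyond the table.
    """
    knots = np.concatenate([[0.0], np.asarray(model.horizons, dtype=float)])
    h = np.concatenate([[0.0], [-math.log(model.s0_table[t]) for t in model.horizons]])
    t = np.asarray(times, dtype=float)
    out = np.interp(t, knots, h)
    last_rate = (h[-1] - h[-2]) / (knots[-1] - knots[-2]) if len(knots) > 1 else 0.0
    beyond = t > knots[-1]
    out = np.where(beyond, h[-1] + last_rate * (t - knots[-1]), out)
    return out


def load_model(source) -> RiskModelSpec:
    """Load a model spec: ``'published'``, ``'recalibrated'``, or a JSON path."""
    if source == "published":
        return published_model()
    if source == "recalibrated":
        return recalibrated_model()
    return RiskModelSpec.from_json(source)


def _packaged(name: str) -> RiskModelSpec:
    with resources.files("arvcrisk").joinpath("data", name).open(encoding="utf-8") as fh:
        return RiskModelSpec.from_dict(json.load(fh))


def published_model() -> RiskModelSpec:
    """The originally published risk equation (5-year baseline survival 0.801)."""
    return _packaged("published_model.json")


def recalibrated_model() -> RiskModelSpec:
    """The baseline-recalibrated equation (5-year baseline survival 0.512)."""
    return _packaged("recalibrated_model.json")
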