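"""Calibration-in-the-large: baseline-survival recalibration.

When a fixed proportional-hazards risk equation systematically under- or
over-estimates risk in a new population, the first-line correction is a
single intercept shift alpha on the log-hazard scale.  Every patient's
cumulative hazard is multiplied by exp(alpha), which rewrites the baseline
survival table as

    S0_new(t) = S0_old(t) ** exp(alpha)

while leaving the covariate coefficients (and hence the risk ranking)
untouched.  ``fit_recalibration`` estimates alpha on a validation cohort,
by default by anchoring at a single horizon: alpha solves

    mean_i S0(anchor) ** (exp(alpha) * exp(LP_i)) = KM(anchor),

so the cohort's average predicted survival under the shifted model equals
the observed Kaplan–Meier survival at the anchor exactly.  An alternative
all-times estimator (intercept-only hazard-offset maximum likelihood with
the model's own baseline) is available via ``method='offset'``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import (
    RiskModelSpec,
    baseline_cumulative_hazard,
    cohort_linear_predictor,
)
from .survival import kaplan_meier

__all__ = ["RecalibrationFit", "fit_recalibration", "apply_recalibration"]

_ALPHA_BRACKET = (-10.0, 10.0)
_ALPHA_XTOL = 1e-10
_S0_FLOOR = 1e-300


@dataclass(frozen=True)
class RecalibrationFit:
    """An estimated log-hazard intercept and the rewritten model."""

    alpha: float
    exp_alpha: float
    anchor_time: float
    model_before: RiskModelSpec
    model_after: RiskModelSpec
    method: str = "anchor"

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "exp_alpha": self.exp_alpha,
            "anchor_time": self.anchor_time,
            "method": self.method,
            "s0_before": {str(t): s for t, s in sorted(self.model_before.s0_table.items())},
            "s0_after": {str(t): s for t, s in sorted(self.model_after.s0_table.items())},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def apply_recalibration(model: RiskModelSpec, alpha: float) -> RiskModelSpec:
    """Rewrite the baseline-survival table as S0(t) ** exp(alpha).

    Coefficients are untouched; the label records the shift.  An entry that
    would underflow to 0 is clipped (with a warning) so the result remains
    a valid model spec.
    """
    ea = math.exp(alpha)
    table = {}
    for t, s in model.s0_table.items():
        new = s**ea
        if new <= 0.0:
            warnings.warn(f"recalibrated S0({t}) underflowed; clipped to {_S0_FLOOR}")
            new = _S0_FLOOR
        table[t] = new
    label = f"{model.label} [recalibrated alpha={alpha:.4f}]".strip()
    return model.with_s0_table(table, label=label)


def _fit_anchor(s0_anchor: float, lp: np.ndarray, s_obs: float) -> float:
    log_s0 = math.log(s0_anchor)
    explp = np.exp(lp)

    def gap(alpha: float) -> float:
        return float(np.mean(np.exp(math.exp(alpha) * explp * log_s0)) - s_obs)

    lo, hi = _ALPHA_BRACKET
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            "observed survival cannot be matched with alpha in [-10, 10]"
        )
    return float(brentq(gap, lo, hi, xtol=_ALPHA_XTOL))


def _fit_offset(model: RiskModelSpec, lp: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    # MLE of a proportional offset against the model's own baseline hazard:
    # exp(alpha) = total events / total model-expected cumulative hazard
    h0 = baseline_cumulative_hazard(model, t)
    expected = float(np.sum(h0 * np.exp(lp)))
    events = float(e.sum())
    return math.log(events / expected)


def fit_recalibration(
    model: RiskModelSpec,
    cohort: pd.DataFrame,
    anchor_time: float = 5.0,
    method: str = "anchor",
) -> RecalibrationFit:
    """Estimate the calibration-in-the-large intercept on a cohort.

    ``method='anchor'`` (default) solves for alpha by bracketed root
    finding so that average predicted survival equals KM survival at
    ``anchor_time``; ``method='offset'`` is the all-times hazard-offset
    MLE.  Raises if the cohort has no events, or (anchor method) if the KM
    survival at the anchor is exactly 0 or 1, where alpha is unbounded.
    """
    t = cohort["time_years"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy(dtype=int)
    if e.sum() < 1:
        raise ValueError("recalibration requires at least one event")
    lp = cohort_linear_predictor(model, cohort)

    if method == "anchor":
        s0_anchor = model.baseline_survival(anchor_time)
        s_obs = kaplan_meier((t, e)).survival_at(anchor_time)
        if s_obs <= 0.0 or s_obs >= 1.0:
            raise ValueError(
                f"observed survival at anchor {anchor_time} is {s_obs}: "
                "alpha is unbounded (boundary)"
            )
        alpha = _fit_anchor(s0_anchor, lp, s_obs)
    elif method == "offset":
        model.baseline_survival(anchor_time)  # validate the anchor is tabulated
        alpha = _fit_offset(model, lp, t, e)
    else:
        raise ValueError(f"unknown method {method!r} (use 'anchor' or 'offset')")

    return RecalibrationFit(
        alpha=alpha,
        exp_alpha=math.exp(alpha),
        anchor_time=float(anchor_time),
        model_before=model,
        model_after=apply_recalibration(model, alpha),
        method=method,
    )
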