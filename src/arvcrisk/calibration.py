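"""Predicted-versus-observed calibration of a fixed risk equation.

Calibration is assessed at the cohort level: at each evaluation time the
model's mean predicted risk across patients is compared with the observed
Kaplan–Meier cumulative event rate.  The summary statistic is the average
of (predicted − observed) over the evaluation grid, with a nonparametric
bootstrap confidence interval (patients resampled with replacement).  A
quartile breakdown (mean predicted vs observed event rate per quartile of
predicted risk) supports the usual bar-style calibration plot.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .models import RiskModelSpec, cohort_linear_predictor, risk_from_lp
from .survival import kaplan_meier

__all__ = [
    "CalibrationResult",
    "QuartileBar",
    "mean_predicted_observed",
    "quartile_calibration",
    "DEFAULT_EVAL_TIMES",
]

#: yearly grid matching the baseline-survival table
DEFAULT_EVAL_TIMES = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class CalibrationResult:
    """Mean predicted−observed difference (probability scale) with CI."""

    mean_diff: float
    ci: tuple[float, float]
    eval_times: tuple[float, ...]
    predicted: tuple[float, ...]
    observed: tuple[float, ...]
    n: int
    n_boot: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci"] = list(self.ci)
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def _observed_rates(t, e, eval_times):
    curve = kaplan_meier((t, e))
    return np.array([1.0 - curve.survival_at(u) for u in eval_times])


def _risk_matrix(model, lp, eval_times):
    return np.column_stack([risk_from_lp(model, lp, u) for u in eval_times])


def mean_predicted_observed(
    model: RiskModelSpec,
    cohort: pd.DataFrame,
    eval_times=DEFAULT_EVAL_TIMES,
    n_boot: int = 1000,
    conf_level: float = 0.95,
    rng: np.random.Generator | int | None = 0,
) -> CalibrationResult:
    """Average predicted−observed event rate over a grid of years.

    Grid times with an empty risk set (beyond the last observed follow-up)
    are dropped with a warning.  ``n_boot = 0`` skips the bootstrap and
    returns a NaN CI.
    """
    if cohort.empty:
        raise ValueError("cohort must be non-empty")
    t = cohort["time_years"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy(dtype=int)
    eval_times = tuple(float(u) for u in eval_times)
    curve = kaplan_meier((t, e))
    # a time past the last observed follow-up carries no information unless
    # the curve has already reached 0 (then S(t) = 0 is determined)
    exhausted = curve.survival_at(curve.max_time) == 0.0
    kept = tuple(u for u in eval_times if u <= t.max() or exhausted)
    if len(kept) < len(eval_times):
        dropped = sorted(set(eval_times) - set(kept))
        warnings.warn(f"evaluation times {dropped} have an empty risk set: dropped")
    if not kept:
        raise ValueError("no evaluation time lies within the observed follow-up")

    lp = cohort_linear_predictor(model, cohort)
    risks = _risk_matrix(model, lp, kept)
    predicted = risks.mean(axis=0)
    observed = _observed_rates(t, e, kept)
    mean_diff = float(np.mean(predicted - observed))

    ci = (float("nan"), float("nan"))
    if n_boot > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        n = t.size
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = gen.integers(0, n, size=n)
            obs_b = _observed_rates(t[idx], e[idx], kept)
            reps[b] = np.mean(risks[idx].mean(axis=0) - obs_b)
        alpha = (1.0 - conf_level) / 2.0
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
        ci = (float(lo), float(hi))

    return CalibrationResult(
        mean_diff=mean_diff,
        ci=ci,
        eval_times=kept,
        predicted=tuple(float(p) for p in predicted),
        observed=tuple(float(o) for o in observed),
        n=int(t.size),
        n_boot=n_boot,
    )


@dataclass(frozen=True)
class QuartileBar:
    """One bar pair of a quartile calibration plot."""

    quartile: int  # 1 (lowest predicted risk) .. 4
    n: int
    mean_predicted: float
    observed_rate: float
    unstable: bool  # risk set empty at the horizon within this quartile


def quartile_calibration(
    model: RiskModelSpec,
    cohort: pd.DataFrame,
    horizon: float = 5.0,
) -> list[QuartileBar]:
    """Mean predicted vs KM-observed event rate per predicted-risk quartile.

    Quartiles split the cohort into four near-equal groups by predicted
    risk at ``horizon``; ties (including a fully homogeneous cohort) are
    broken by row order so the partition is always near-equal.
    """
    if len(cohort) < 8:
        raise ValueError("quartile calibration needs at least 8 patients")
    lp = cohort_linear_predictor(model, cohort)
    risks = np.asarray(risk_from_lp(model, lp, horizon))
    ranks = pd.Series(risks).rank(method="first")
    quartile = pd.qcut(ranks, 4, labels=False) + 1
    t = cohort["time_years"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy(dtype=int)

    bars = []
    for q in (1, 2, 3, 4):
        mask = (quartile == q).to_numpy()
        curve = kaplan_meier((t[mask], e[mask]))
        unstable = horizon > curve.max_time
        bars.append(
            QuartileBar(
                quartile=q,
                n=int(mask.sum()),
                mean_predicted=float(risks[mask].mean()),
                observed_rate=1.0 - curve.survival_at(min(horizon, curve.max_time)),
                unstable=unstable,
            )
        )
    return bars


def quartile_bars_to_frame(bars: list[QuartileBar]) -> pd.DataFrame:
    """TSV-ready table for re-plotting a quartile calibration chart."""
    return pd.DataFrame([asdict(b) for b in bars])
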