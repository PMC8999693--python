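"""Nonparametric machinery for right-censored follow-up.

Kaplan–Meier product-limit estimation with Greenwood variance and log(−log)
confidence intervals, the two-sample log-rank test, and Harrell's
concordance index for censored outcomes.  The concordance convention here
is the classic one: a pair is usable when the strictly shorter follow-up
time ends in an event; concordant pairs (higher risk score on the earlier
event) count 1, tied scores count 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

__all__ = [
    "FollowUpRecord",
    "KaplanMeierCurve",
    "EventRateEstimate",
    "LogRankResult",
    "ConcordanceUndefinedError",
    "kaplan_meier",
    "event_rate_at",
    "log_rank_test",
    "concordance_index",
    "concordance_with_ci",
]


@dataclass(frozen=True)
class FollowUpRecord:
    """Right-censored outcome: follow-up time in years and event indicator."""

    time_years: float
    event: int
    endpoint_label: str = "icd_therapy"

    def __post_init__(self) -> None:
        if self.time_years <= 0:
            raise ValueError("time_years must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


class ConcordanceUndefinedError(ValueError):
    """No usable pairs (e.g. all records censored): C-statistic undefined."""


def _extract_times_events(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        t = records["time_years"].to_numpy(dtype=float)
        e = records["event"].to_numpy(dtype=int)
    else:
        records = list(records)
        if records and hasattr(records[0], "time_years"):
            t = np.array([r.time_years for r in records], dtype=float)
            e = np.array([r.event for r in records], dtype=int)
        else:  # (times, events) pair of sequences
            t, e = records
            t = np.asarray(t, dtype=float)
            e = np.asarray(e, dtype=int)
    if t.size == 0:
        raise ValueError("at least one follow-up record is required")
    if (t <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return t, e


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit survival estimate.

    Arrays are aligned per distinct event time (steps only).  ``survival``
    is right-continuous: S(t) is the value at the last step at or before t,
    and 1 before the first event.  ``greenwood_var`` is the Greenwood
    variance of S at each step; the final step is NaN when S reaches 0.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int
    total_events: int
    max_time: float
    conf_level: float = 0.95

    def _step_index(self, t: float) -> int:
        # index of last event time <= t, or -1 (before first event)
        return int(np.searchsorted(self.event_times, t, side="right")) - 1

    def survival_at(self, t: float) -> float:
        i = self._step_index(t)
        return 1.0 if i < 0 else float(self.survival[i])

    def variance_at(self, t: float) -> float:
        i = self._step_index(t)
        return 0.0 if i < 0 else float(self.greenwood_var[i])

    def ci_at(self, t: float) -> tuple[float, float]:
        i = self._step_index(t)
        if i < 0:
            return (1.0, 1.0)
        return float(self.ci_lower[i]), float(self.ci_upper[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
                "lower": self.ci_lower,
                "upper": self.ci_upper,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _loglog_ci(surv: np.ndarray, var: np.ndarray, conf_level: float):
    """log(−log) transformed pointwise CI, bounded inside [0, 1]."""
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    lower = np.empty_like(surv)
    upper = np.empty_like(surv)
    for i, (s, v) in enumerate(zip(surv, var)):
        if not (0.0 < s < 1.0) or not np.isfinite(v):
            lower[i] = upper[i] = s
            continue
        se = math.sqrt(v) / (s * abs(math.log(s)))
        lower[i] = s ** math.exp(z * se)
        upper[i] = s ** math.exp(-z * se)
    return lower, upper


def kaplan_meier(records, conf_level: float = 0.95) -> KaplanMeierCurve:
    """Product-limit estimate from right-censored records.

    ``records`` may be a cohort DataFrame (``time_years``/``event``
    columns), a sequence of :class:`FollowUpRecord`, or a ``(times,
    events)`` pair of arrays.  Ties between events and censorings at the
    same time follow the standard convention: events happen first.
    """
    t, e = _extract_times_events(records)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    n = t.size

    # distinct times, deaths per time, at-risk = everyone with time >= u
    uniq, first_idx = np.unique(t, return_index=True)
    d_all = np.add.reduceat(e, first_idx)
    risk_all = n - first_idx
    has_event = d_all > 0
    event_times = uniq[has_event]
    d = d_all[has_event]
    at_risk = risk_all[has_event]

    if event_times.size == 0:
        return KaplanMeierCurve(
            event_times=np.empty(0),
            survival=np.empty(0),
            at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
            greenwood_var=np.empty(0),
            ci_lower=np.empty(0),
            ci_upper=np.empty(0),
            n=n,
            total_events=0,
            max_time=float(t.max()),
            conf_level=conf_level,
        )

    surv = np.cumprod(1.0 - d / at_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.nan)
        var = surv**2 * np.cumsum(terms)
    var = np.where(surv == 0.0, np.nan, var)
    lower, upper = _loglog_ci(surv, var, conf_level)
    return KaplanMeierCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=d,
        greenwood_var=var,
        ci_lower=lower,
        ci_upper=upper,
        n=n,
        total_events=int(e.sum()),
        max_time=float(t.max()),
        conf_level=conf_level,
    )


@dataclass(frozen=True)
class EventRateEstimate:
    """Cumulative event probability 1 − S(t) with a transformed CI."""

    rate: float
    ci: tuple[float, float]
    horizon: float
    extrapolated: bool = False


def event_rate_at(curve: KaplanMeierCurve, horizon: float) -> EventRateEstimate:
    """1 − S(horizon) with log(−log)-transformed CI (right-continuous step).

    A horizon beyond the last observed time returns the last value, flagged
    ``extrapolated``.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    extrapolated = horizon > curve.max_time
    t = min(horizon, curve.max_time)
    s_lo, s_up = curve.ci_at(t)
    return EventRateEstimate(
        rate=1.0 - curve.survival_at(t),
        ci=(1.0 - s_up, 1.0 - s_lo),
        horizon=horizon,
        extrapolated=extrapolated,
    )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float


def log_rank_test(group_a, group_b) -> LogRankResult:
    """Two-sample log-rank chi-square test (1 df)."""
    ta, ea = _extract_times_events(group_a)
    tb, eb = _extract_times_events(group_b)
    if ea.sum() + eb.sum() == 0:
        return LogRankResult(statistic=0.0, p_value=1.0)
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def concordance_index(risks, records) -> float:
    """Harrell's C for censored data.

    Usable pairs are those where the strictly shorter time ends in an
    event; the pair is concordant when that patient carries the higher risk
    score, and tied scores count 1/2.  Pairs with identical follow-up times
    are not usable.
    """
    t, e = _extract_times_events(records)
    r = np.asarray(risks, dtype=float)
    if r.shape != t.shape:
        raise ValueError("risks and records must be aligned")
    # usable[i, j]: t_i < t_j and patient i had the event
    usable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ConcordanceUndefinedError("no usable pairs: C-statistic undefined")
    concordant = (r[:, None] > r[None, :]) & usable
    tied = (r[:, None] == r[None, :]) & usable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


def concordance_with_ci(
    risks,
    records,
    n_boot: int = 1000,
    conf_level: float = 0.95,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, tuple[float, float]]:
    """C-statistic with a nonparametric (patient-resampling) bootstrap CI."""
    t, e = _extract_times_events(records)
    r = np.asarray(risks, dtype=float)
    c = concordance_index(r, (t, e))
    if n_boot <= 0:
        return c, (math.nan, math.nan)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = t.size
    reps = []
    for _ in range(n_boot):
        idx = gen.integers(0, n, size=n)
        try:
            reps.append(concordance_index(r[idx], (t[idx], e[idx])))
        except ConcordanceUndefinedError:
            continue
    alpha = (1.0 - conf_level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return c, (float(lo), float(hi))
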