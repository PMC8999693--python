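"""End-to-end external validation of the risk equation on a cohort.

Mirrors the structure of a model-validation study: impute missing PVC
counts by the cohort median, stratify into primary/secondary prevention,
compute per-stratum Kaplan–Meier event rates, C-statistic and
predicted-vs-observed calibration, recalibrate the baseline survival on
the secondary-prevention stratum, re-evaluate calibration under the
recalibrated model, and repeat the whole analysis with imputed-PVC
patients excluded (sensitivity analysis).  The result is a single
machine-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_EVAL_TIMES,
    mean_predicted_observed,
    quartile_calibration,
)
from .cohort import impute_pvc_median, stratify_by_prevention
from .models import RiskModelSpec, cohort_linear_predictor, risk_from_lp
from .recalibration import fit_recalibration
from .survival import (
    ConcordanceUndefinedError,
    concordance_with_ci,
    event_rate_at,
    kaplan_meier,
    log_rank_test,
)

__all__ = ["run_validation", "report_to_markdown", "report_to_tsv"]

_RATE_HORIZONS = (1.0, 2.0, 5.0)
_MIN_EVENTS = 2


def _cohort_hash(cohort: pd.DataFrame, model: RiskModelSpec, seed: int) -> str:
    payload = cohort.to_csv(index=False) + json.dumps(model.to_dict(), sort_keys=True) + str(seed)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stratum_block(
    df: pd.DataFrame,
    model: RiskModelSpec,
    horizon: float,
    eval_times,
    n_boot: int,
    seed_seq: np.random.SeedSequence,
) -> dict:
    n = int(len(df))
    events = int(df["event"].sum()) if n else 0
    block: dict = {"n": n, "events": events, "available": True}
    if n == 0 or events < _MIN_EVENTS:
        block["available"] = False
        return block

    curve = kaplan_meier(df)
    block["km_event_rates"] = {}
    for h in _RATE_HORIZONS:
        est = event_rate_at(curve, h)
        block["km_event_rates"][str(int(h))] = {
            "rate": est.rate,
            "ci": list(est.ci),
            "extrapolated": est.extrapolated,
        }

    rng_c, rng_cal = (np.random.default_rng(s) for s in seed_seq.spawn(2))
    lp = cohort_linear_predictor(model, df)
    risks = np.asarray(risk_from_lp(model, lp, horizon))
    try:
        c, c_ci = concordance_with_ci(risks, df, n_boot=n_boot, rng=rng_c)
        block["c_statistic"] = {"value": c, "ci": list(c_ci)}
    except ConcordanceUndefinedError:
        block["c_statistic"] = None

    cal = mean_predicted_observed(model, df, eval_times=eval_times, n_boot=n_boot, rng=rng_cal)
    block["calibration"] = cal.to_dict()
    if n >= 8:
        block["quartiles"] = [dataclasses.asdict(b) for b in quartile_calibration(model, df, horizon)]
    else:
        block["quartiles"] = None
    return block


def run_validation(
    cohort: pd.DataFrame,
    model: RiskModelSpec,
    seed: int = 0,
    eval_times=DEFAULT_EVAL_TIMES,
    anchor_time: float = 5.0,
    recalibration_stratum: str = "secondary",
    n_boot: int = 1000,
    sensitivity: bool = True,
) -> dict:
    """Run the full validation workflow and return the report as a dict.

    Deterministic given ``seed`` (all bootstrap streams are spawned from
    it).  A stratum with fewer than two events has its metrics marked
    unavailable; an empty recalibration stratum disables the
    recalibration block without failing the run.
    """
    root = np.random.SeedSequence(seed)
    imputed, n_imputed = impute_pvc_median(cohort)
    imputed_mask = cohort["pvc_24h"].isna().to_numpy()

    report: dict = {
        "model": model.to_dict(),
        "provenance": {
            "seed": int(seed),
            "config_hash": _cohort_hash(cohort, model, seed),
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "n_imputed_pvc": int(n_imputed),
        },
    }
    report["strata"] = _analyse(imputed, model, root.spawn(1)[0], eval_times, anchor_time,
                                recalibration_stratum, n_boot)

    if sensitivity:
        subset = imputed.loc[~imputed_mask]
        report["sensitivity"] = _analyse(subset, model, root.spawn(2)[1], eval_times,
                                         anchor_time, recalibration_stratum, n_boot)
        report["sensitivity"]["n_excluded"] = int(imputed_mask.sum())
    return report


def _analyse(
    df: pd.DataFrame,
    model: RiskModelSpec,
    seed_seq: np.random.SeedSequence,
    eval_times,
    anchor_time: float,
    recalibration_stratum: str,
    n_boot: int,
) -> dict:
    primary, secondary = stratify_by_prevention(df)
    strata = {"all": df, "primary": primary, "secondary": secondary}
    children = seed_seq.spawn(len(strata) + 1)
    seqs = dict(zip(strata, children))
    out: dict = {}
    for name, sub in strata.items():
        out[name] = _stratum_block(sub, model, anchor_time, eval_times, n_boot, seqs[name])

    if len(primary) and len(secondary) and (df["event"].sum() > 0):
        lr = log_rank_test(primary, secondary)
        out["logrank_primary_vs_secondary"] = {"statistic": lr.statistic, "p_value": lr.p_value}
    else:
        out["logrank_primary_vs_secondary"] = None

    recal_df = strata.get(recalibration_stratum, secondary)
    recal_block: dict = {"stratum": recalibration_stratum, "available": False}
    if len(recal_df) and recal_df["event"].sum() >= _MIN_EVENTS:
        try:
            fit = fit_recalibration(model, recal_df, anchor_time=anchor_time)
        except ValueError as exc:
            recal_block["error"] = str(exc)
        else:
            rng_post = np.random.default_rng(children[-1])
            post = mean_predicted_observed(
                fit.model_after, recal_df, eval_times=eval_times, n_boot=n_boot, rng=rng_post
            )
            recal_block.update(
                {
                    "available": True,
                    **fit.to_dict(),
                    "post_calibration": post.to_dict(),
                }
            )
    out["recalibration"] = recal_block
    return out


def _fmt(x, nd=3):
    return "NA" if x is None else f"{x:.{nd}f}"


def report_to_markdown(report: dict) -> str:
    """Human-readable summary of a validation report."""
    lines = [f"# Validation report — {report['model']['label']}", ""]
    for section in ("strata", "sensitivity"):
        if section not in report:
            continue
        lines.append(f"## {section}")
        for name in ("all", "primary", "secondary"):
            blk = report[section].get(name)
            if blk is None:
                continue
            lines.append(f"### {name} (n={blk['n']}, events={blk['events']})")
            if not blk.get("available"):
                lines.append("metrics unavailable (fewer than 2 events)")
                continue
            c = blk.get("c_statistic")
            if c:
                lines.append(f"- C-statistic {c['value']:.3f} (95% CI {c['ci'][0]:.3f}–{c['ci'][1]:.3f})")
            cal = blk["calibration"]
            lines.append(
                f"- mean predicted−observed {cal['mean_diff']:.3f} "
                f"(95% CI {cal['ci'][0]:.3f}, {cal['ci'][1]:.3f})"
            )
            for h, est in blk["km_event_rates"].items():
                lines.append(
                    f"- KM event rate at {h}y: {est['rate']:.3f} "
                    f"({est['ci'][0]:.3f}–{est['ci'][1]:.3f})"
                )
        rec = report[section].get("recalibration", {})
        if rec.get("available"):
            post = rec["post_calibration"]
            lines.append(
                f"- recalibration ({rec['stratum']}): alpha={rec['alpha']:.4f}, "
                f"post mean diff {post['mean_diff']:.3f} "
                f"(95% CI {post['ci'][0]:.3f}, {post['ci'][1]:.3f})"
            )
        lines.append("")
    return "\n".join(lines)


def report_to_tsv(report: dict) -> str:
    """Flat TSV of the headline per-stratum metrics."""
    rows = []
    for section in ("strata", "sensitivity"):
        if section not in report:
            continue
        for name in ("all", "primary", "secondary"):
            blk = report[section].get(name)
            if blk is None or not blk.get("available"):
                continue
            c = blk.get("c_statistic") or {}
            cal = blk["calibration"]
            rows.append(
                {
                    "section": section,
                    "stratum": name,
                    "n": blk["n"],
                    "events": blk["events"],
                    "c_statistic": c.get("value"),
                    "mean_diff": cal["mean_diff"],
                    "mean_diff_lo": cal["ci"][0],
                    "mean_diff_hi": cal["ci"][1],
                }
            )
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)
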