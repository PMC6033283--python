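"""Consecutive-classifier treatment stratification.

Two locked single-sample predictors are applied in sequence: first the model
trained in RT-untreated patients estimates the recurrence risk without
radiotherapy — low-risk samples form the "No-RT" group.  For the remaining
samples the model trained in RT-treated patients (a radioresistance test) is
applied: low risk under RT means "Give-RT", high risk even with RT means
"More-treatment" (candidates for escalation, e.g. mastectomy or more systemic
therapy).  RT benefit is then evaluated per group by Kaplan-Meier / log-rank
split on actual RT, plus one Cox model with group indicators, RT and
group x RT interaction terms.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import validate_annotation
from .ktsp import SSPModel, predict
from .survival import cox_fit, km_fit, logrank_test

logger = logging.getLogger(__name__)

GROUPS = ("No-RT", "Give-RT", "More-treatment")


def _er_part(stratum: str) -> str:
    return stratum.split("RT")[0]


def assign_groups(
    expr,
    ssp_rtminus: SSPModel,
    ssp_rtplus: SSPModel,
    allow_stratum_mismatch: bool = False,
) -> pd.DataFrame:
    """Assign every sample to No-RT / Give-RT / More-treatment.

    Pure function of the two model predictions: low by the RT- model means
    No-RT (RT+ model not evaluated); otherwise low by the RT+ model means
    Give-RT, high means More-treatment.
    """
    if not allow_stratum_mismatch and _er_part(ssp_rtminus.stratum) != _er_part(ssp_rtplus.stratum):
        raise ValueError(
            f"models target different ER strata ({ssp_rtminus.stratum} vs "
            f"{ssp_rtplus.stratum}); pass allow_stratum_mismatch=True to override"
        )
    pred_minus = predict(ssp_rtminus, expr)
    pred_plus = predict(ssp_rtplus, expr)
    rows = []
    for sample in pred_minus.index:
        low_without_rt = not pred_minus.loc[sample, "high_risk"]
        if low_without_rt:
            rows.append((sample, "No-RT", "low", "not_evaluated"))
        else:
            high_with_rt = bool(pred_plus.loc[sample, "high_risk"])
            group = "More-treatment" if high_with_rt else "Give-RT"
            rows.append((sample, group, "high", "high" if high_with_rt else "low"))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "rtminus_prediction", "rtplus_prediction"]
    )


def evaluate_rt_benefit(assignments: pd.DataFrame, annot: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Evaluate the RT effect within each treatment group.

    Per group: KM curves split by actual RT with the log-rank p for the RT
    effect; a group with only one RT arm is reported prognostic-only.
    Overall: a Cox model with Give-RT and More-treatment indicators, RT, and
    the two group x RT interactions.  Returns one JSON-serializable report.
    """
    annot = validate_annotation(annot)
    merged = assignments.merge(annot, on="sample_id", how="inner", validate="1:1")
    if len(merged) < len(assignments):
        missing = set(assignments["sample_id"]) - set(merged["sample_id"])
        raise ValueError(f"assignments without annotation: {sorted(missing)}")

    report: dict = {"groups": {}, "cox_interaction": None}
    for group in GROUPS:
        sub = merged[merged["group"] == group]
        if sub.empty:
            warnings.warn(f"treatment group {group!r} is empty; skipped", stacklevel=2)
            report["groups"][group] = {"n": 0, "skipped": True}
            continue
        entry: dict = {"n": int(len(sub)), "skipped": False}
        t = sub["time_years"].to_numpy()
        e = sub["ibtr_event"].to_numpy()
        rt = sub["rt"].to_numpy()
        both_arms = rt.any() and (~rt).any()
        entry["prognostic_only"] = not both_arms
        if both_arms and e.sum() > 0:
            curves = km_fit(t, e, np.where(rt, "RT+", "RT-"))
            chi2, p = logrank_test(t, e, rt)
            entry["logrank_rt"] = {"chi2": chi2, "p": p, "significant": p < alpha}
            entry["risk_10y"] = {arm: curves[arm].risk_at(10.0) for arm in curves}
        else:
            curve = km_fit(t, e)
            entry["risk_10y"] = {"all": curve.risk_at(10.0)}
        report["groups"][group] = entry

    data = merged.copy()
    data["give_rt_group"] = (data["group"] == "Give-RT").astype(float)
    data["more_treatment_group"] = (data["group"] == "More-treatment").astype(float)
    data["rt_given"] = data["rt"].astype(float)
    try:
        fit = cox_fit(
            data,
            duration_col="time_years",
            event_col="ibtr_event",
            covariates=["give_rt_group", "more_treatment_group", "rt_given"],
            interactions=[("rt_given", "give_rt_group"), ("rt_given", "more_treatment_group")],
        )
        report["cox_interaction"] = {
            "coefficients": fit.coefficients,
            "hazard_ratios": fit.hazard_ratios,
            "ci95": {k: list(v) for k, v in fit.ci95.items()},
            "p_values": fit.p_values,
            "n_events": fit.n_events,
        }
    except (ValueError, RuntimeError) as err:
        logger.warning("Cox interaction model not evaluable: %s", err)
        report["cox_interaction"] = {"error": str(err)}
    return report
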