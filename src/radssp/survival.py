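"""Survival evaluation layer: Kaplan-Meier, log-rank, Cox PH, ROC/AUC.

Thin, validated wrappers around lifelines (product-limit estimator, log-rank
statistic, Cox partial-likelihood fit with Efron tie handling) and
scikit-learn (ROC), returning plain result objects.  The endpoint throughout
is ipsilateral breast tumor recurrence (IBTR), with time in years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    event_times: np.ndarray   # distinct times with >=1 event
    survival: np.ndarray      # S(t) at those times
    at_risk: np.ndarray       # n at risk just before each event time
    n_events: np.ndarray      # events at each time
    n_samples: int = 0

    def risk_at(self, t: float) -> float:
        """Cumulative risk 1 - S(t) at the last event time <= t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float(1.0 - self.survival[idx])


@dataclass
class CoxFit:
    coefficients: dict
    hazard_ratios: dict
    ci95: dict           # name -> (lower HR, upper HR)
    p_values: dict
    converged: bool = True
    n_events: int = 0

    def __post_init__(self):
        for name, hr in self.hazard_ratios.items():
            lo, hi = self.ci95[name]
            if not (hr > 0 and lo <= hr <= hi):
                raise ValueError(f"inconsistent HR/CI for {name}")


def _check_time_event(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    return t, e


def km_fit(time, event, group=None):
    """Kaplan-Meier curves; returns a KMCurve, or dict group -> KMCurve."""
    t, e = _check_time_event(time, event)
    if group is None:
        return _km_one(t, e)
    g = np.asarray(group)
    out = {}
    for level in pd.unique(g):
        mask = g == level
        if mask.sum() == 0:
            raise ValueError(f"group {level!r} is empty")
        out[level] = _km_one(t[mask], e[mask])
    if not out:
        raise ValueError("no groups supplied")
    return out


def _km_one(t: np.ndarray, e: np.ndarray) -> KMCurve:
    if t.size == 0:
        raise ValueError("empty group in km_fit")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    with_events = table[table["observed"] > 0]
    times = with_events.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=with_events["at_risk"].to_numpy(dtype=int),
        n_events=with_events["observed"].to_numpy(dtype=int),
        n_samples=int(t.size),
    )


def logrank_test(time, event, group):
    """Log-rank test; 1 df for two groups, (g - 1) df for g groups."""
    t, e = _check_time_event(time, event)
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    for level in levels:
        if (g == level).sum() == 0:
            raise ValueError(f"group {level!r} is empty")
    if e.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    if len(levels) == 2:
        m = g == levels[0]
        res = _ll_logrank(t[m], t[~m], event_observed_A=e[m], event_observed_B=e[~m])
    else:
        res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list,
    interactions: list | None = None,
    events_per_coef: int = 5,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with optional interactions.

    ``interactions`` is a list of (a, b) covariate name pairs; each adds a
    product column named ``"a:b"``.  Guards: enough events per coefficient,
    no constant covariate, convergence (monotone likelihood raises).
    """
    df = data[[duration_col, event_col] + list(covariates)].copy()
    for col in covariates:
        df[col] = df[col].astype(float)
    names = list(covariates)
    for a, b in interactions or []:
        df[f"{a}:{b}"] = df[a] * df[b]
        names.append(f"{a}:{b}")
    for col in names:
        if df[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant; no information")
    n_events = int(df[event_col].astype(bool).sum())
    if n_events < events_per_coef * len(names):
        raise ValueError(
            f"{n_events} events for {len(names)} coefficients; "
            f"need >= {events_per_coef} events per coefficient"
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # tight Newton tolerance: partial-likelihood maximizer to ~1e-8
            cph.fit(
                df,
                duration_col=duration_col,
                event_col=event_col,
                fit_options={"precision": 1e-9},
            )
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model did not converge: {err}") from err
    summary = cph.summary
    coefs = {n: float(summary.loc[n, "coef"]) for n in names}
    if max(abs(c) for c in coefs.values()) > 20:
        raise RuntimeError(
            "Cox fit produced an extreme coefficient (likely monotone "
            f"likelihood / separation): {coefs}"
        )
    return CoxFit(
        coefficients=coefs,
        hazard_ratios={n: float(np.exp(coefs[n])) for n in names},
        ci95={
            n: (
                float(np.exp(summary.loc[n, "coef lower 95%"])),
                float(np.exp(summary.loc[n, "coef upper 95%"])),
            )
            for n in names
        },
        p_values={n: float(summary.loc[n, "p"]) for n in names},
        converged=True,
        n_events=n_events,
    )


def roc_auc(scores, outcome):
    """AUC as the Mann-Whitney concordance (ties get half credit) + curve."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcome must be 1-d arrays of equal length")
    if y.all() or not y.any():
        raise ValueError("outcome must contain both classes")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return auc, curve
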