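"""Kaplan-Meier estimation, log-rank testing, and Cox regression.

Thin, validated wrappers around lifelines.  Ties in the Cox partial
likelihood use the Efron approximation; confidence intervals are Wald
intervals on the log-hazard scale.  Subjects with time 0 and no event
carry no information and are dropped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io_formats import SurvivalTable

__all__ = ["KmCurve", "CoxResult", "km_estimate", "logrank", "cox_hr"]


@dataclass
class KmCurve:
    """One group's product-limit survival curve."""

    label: str
    times: np.ndarray        # distinct observed times (events and censorings)
    at_risk: np.ndarray      # risk-set size just before each time
    survival: np.ndarray     # S(t) immediately after each time
    censor_times: np.ndarray
    n: int
    n_events: int

    def __post_init__(self):
        if len(self.survival) and (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival function must be non-increasing")


@dataclass
class CoxResult:
    coef: float              # log hazard ratio
    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_lr: float
    n: int
    n_events: int

    def __post_init__(self):
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval must contain the HR")


def _clean(table: SurvivalTable) -> pd.DataFrame:
    df = table.data[["time", "event"]].copy()
    degenerate = (df["time"] == 0) & (df["event"] == 0)
    if degenerate.any():
        warnings.warn(
            f"dropping {int(degenerate.sum())} subject(s) with time 0 and no event",
            stacklevel=3,
        )
        df = df.loc[~degenerate]
    return df


def _align_groups(df: pd.DataFrame, groups) -> pd.Series:
    g = pd.Series(groups)
    missing = df.index.difference(g.index)
    if len(missing):
        raise ValueError(f"no group label for sample(s) {list(missing[:5])}")
    return g.loc[df.index].astype(str)


def km_estimate(survival: SurvivalTable, groups) -> list[KmCurve]:
    """Product-limit survival estimate per group (ties decrement together)."""
    df = _clean(survival)
    g = _align_groups(df, groups)
    curves = []
    for label in pd.unique(g):
        sub = df.loc[g == label]
        if (sub["event"] == 0).all():
            warnings.warn(f"group {label!r} has no events; curve stays at 1", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(label))
        times = kmf.event_table.index.to_numpy(dtype=float)
        keep = times > 0  # lifelines inserts a t=0 row
        et = kmf.event_table.loc[keep]
        surv = kmf.survival_function_at_times(times[keep]).to_numpy(dtype=float)
        curves.append(KmCurve(
            label=str(label),
            times=times[keep],
            at_risk=et["at_risk"].to_numpy(dtype=float),
            survival=surv,
            censor_times=np.sort(sub.loc[sub["event"] == 0, "time"].to_numpy(dtype=float)),
            n=len(sub),
            n_events=int(sub["event"].sum()),
        ))
    return curves


def logrank(survival: SurvivalTable, groups):
    """Two-group log-rank test; returns (chi2, p).

    chi2 = (O - E)^2 / V with the hypergeometric variance summed over
    event times; p from the chi-square distribution with 1 df.
    """
    df = _clean(survival)
    g = _align_groups(df, groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError("log-rank comparison requires exactly 2 groups")
    a = df.loc[g == levels[0]]
    b = df.loc[g == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if int(df["event"].sum()) == 0:
        raise ValueError("no events observed")
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_hr(survival: SurvivalTable, covariate, type: str = "continuous") -> CoxResult:
    """Univariable Cox proportional-hazards fit (Efron tie handling).

    ``type='binary'`` expects a two-level covariate (e.g. the low/high
    score group, coded so the HR is high vs low); ``'continuous'``
    returns the hazard ratio per unit covariate.
    """
    df = _clean(survival)
    cov = pd.Series(covariate)
    missing = df.index.difference(cov.index)
    if len(missing):
        raise ValueError(f"no covariate for sample(s) {list(missing[:5])}")
    x = cov.loc[df.index]
    if type == "binary":
        levels = pd.unique(x)
        if len(levels) != 2:
            raise ValueError("binary covariate must have exactly 2 levels")
        if set(levels) == {"low", "high"}:
            x = (x == "high").astype(float)
        else:
            x = (x == levels[1]).astype(float)
    elif type == "continuous":
        x = pd.to_numeric(x)
    else:
        raise ValueError(f"unknown covariate type {type!r}")
    if x.nunique() < 2:
        raise ValueError("constant covariate")
    n_events = int(df["event"].sum())
    if n_events < 10:
        warnings.warn(f"only {n_events} events; estimates may be unstable", stacklevel=2)

    fit_df = pd.DataFrame({"time": df["time"], "event": df["event"], "x": x.astype(float)})
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = 1.959963984540054
    return CoxResult(
        coef=coef,
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_wald=float(cph.summary.loc["x", "p"]),
        p_lr=float(cph.log_likelihood_ratio_test().p_value),
        n=len(fit_df),
        n_events=n_events,
    )
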