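"""Kaplan–Meier estimation and the two-group log-rank test.

The product-limit curve, Greenwood variance and complementary log-log 95%
confidence band are computed directly (the conventions below are fixed:
right-continuous steps, censorings at an event time leave the risk set
after the deaths at that time). The log-rank statistic delegates to
lifelines; an independent event-table tabulation backs it in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from lifelines.statistics import logrank_test as _lifelines_logrank


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray          # distinct death times, ascending
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray       # S(t) at each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_subjects: int
    max_observed: float        # last observed time, event or censoring


def km_estimate(table: pd.DataFrame, alpha: float = 0.05, ci_scale: str = "cloglog") -> KMCurve:
    """Kaplan–Meier curve from a table with ``time`` and ``event`` columns.

    Greenwood's formula gives Var(Ŝ); the confidence band is computed on the
    requested scale: ``"cloglog"`` (default, exponential Greenwood),
    ``"log"``, or ``"plain"`` (linear, clipped to [0, 1]).
    """
    times = np.asarray(table["time"], dtype=float)
    events = np.asarray(table["event"], dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival table")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    death_times = np.unique(times[events == 1])

    n = len(times)
    surv = 1.0
    green_sum = 0.0
    at_risk_l, deaths_l, surv_l, var_l, lo_l, hi_l = [], [], [], [], [], []
    z = stats.norm.ppf(1 - alpha / 2)
    for t in death_times:
        n_i = int(np.sum(times >= t))      # censorings at t still at risk
        d_i = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d_i / n_i
        if n_i > d_i:
            green_sum += d_i / (n_i * (n_i - d_i))
            var = surv**2 * green_sum
        else:
            green_sum = np.inf
            var = 0.0 if surv == 0.0 else np.inf
        if 0.0 < surv < 1.0 and np.isfinite(green_sum):
            if ci_scale == "cloglog":
                se_cll = np.sqrt(green_sum) / abs(np.log(surv))
                theta = np.log(-np.log(surv))
                lo = np.exp(-np.exp(theta + z * se_cll))
                hi = np.exp(-np.exp(theta - z * se_cll))
            elif ci_scale == "log":
                se_log = np.sqrt(green_sum)
                lo = surv * np.exp(-z * se_log)
                hi = surv * np.exp(z * se_log)
            elif ci_scale == "plain":
                half = z * np.sqrt(var)
                lo, hi = surv - half, surv + half
            else:
                raise ValueError(f"unknown ci_scale {ci_scale!r}")
            lo, hi = max(0.0, min(lo, 1.0)), max(0.0, min(hi, 1.0))
        else:
            lo = hi = surv
        at_risk_l.append(n_i)
        deaths_l.append(d_i)
        surv_l.append(surv)
        var_l.append(var)
        lo_l.append(lo)
        hi_l.append(hi)

    return KMCurve(
        times=death_times,
        at_risk=np.array(at_risk_l),
        deaths=np.array(deaths_l),
        survival=np.array(surv_l),
        variance=np.array(var_l),
        ci_lower=np.array(lo_l),
        ci_upper=np.array(hi_l),
        n_subjects=n,
        max_observed=float(times.max()),
    )


def survival_at(curve: KMCurve, t: float) -> tuple[float, tuple[float, float], bool]:
    """Right-continuous step evaluation of Ŝ(t) with its CI.

    Returns (estimate, (lower, upper), extrapolated); ``extrapolated`` is
    True when ``t`` exceeds the last observed time, in which case the last
    value is carried forward.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    extrapolated = t > curve.max_observed
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0, (1.0, 1.0), extrapolated
    return (
        float(curve.survival[idx]),
        (float(curve.ci_lower[idx]), float(curve.ci_upper[idx])),
        extrapolated,
    )


def median_split(scores: pd.Series) -> pd.Series:
    """Label each subject ``"low"`` (score ≤ median) or ``"high"``.

    Ties at the median go to the low group; all-equal scores raise, because
    a one-group split cannot feed the log-rank test.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 subjects to split")
    med = scores.median()
    labels = pd.Series(np.where(scores <= med, "low", "high"), index=scores.index, name="group")
    if labels.nunique() < 2:
        raise ValueError("all scores equal: median split yields a single group")
    return labels


def logrank(table: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Two-group log-rank test; returns (chi², p) with 1 df."""
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(groups)}")
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _lifelines_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def km_to_frame(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.times,
            "at_risk": curve.at_risk,
            "deaths": curve.deaths,
            "survival": curve.survival,
            "greenwood_var": curve.variance,
            "ci_lower": curve.ci_lower,
            "ci_upper": curve.ci_upper,
        }
    )
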