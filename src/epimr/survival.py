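"""Kaplan–Meier estimation, log-rank testing and expression stratification.

Patients are split into HIGH / MID / LOW strata by the fold change of a
focal gene's expression against the cohort median (HIGH: fc > 2, LOW:
fc < 0.5 by default; both thresholds configurable, boundaries map to MID).
Survival curves use the product-limit estimator; group comparison uses the
k-group log-rank (Mantel–Cox / Mantel–Haenszel) test with the standard
simultaneous-risk-set handling of tied event times (censoring ties break
after events at the same time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StrataConfig:
    high_fc: float = 2.0
    low_fc: float = 0.5

    def __post_init__(self) -> None:
        if not (self.high_fc > self.low_fc > 0):
            raise ValueError("thresholds must satisfy high_fc > low_fc > 0")


def stratify_by_expression(
    table: pd.DataFrame, config: StrataConfig | None = None
) -> pd.Series:
    """HIGH / MID / LOW labels from fold change vs the cohort median.

    fc = expr / median(expr); HIGH iff fc > high_fc, LOW iff fc < low_fc,
    MID otherwise (strict inequalities: boundary values are MID).
    """
    config = config or StrataConfig()
    if len(table) == 0:
        raise ValueError("empty survival table")
    median = float(np.median(table["expr"]))
    if median == 0:
        raise ValueError("median expression is zero; fold change undefined")
    fc = table["expr"] / median
    labels = np.where(fc > config.high_fc, "HIGH", np.where(fc < config.low_fc, "LOW", "MID"))
    return pd.Series(labels, index=table.index, name="stratum")


def km_estimator(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with columns ``time``,
    ``n_at_risk``, ``n_events`` and ``survival``; censored times reduce the
    risk set without producing a step. With no events at all a flat S = 1
    curve is returned with a warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time <= 0).any():
        raise ValueError("times must be positive")
    if event.sum() == 0:
        warnings.warn("no events observed; survival curve is flat at 1")
        return pd.DataFrame(columns=["time", "n_at_risk", "n_events", "survival"])
    order = np.lexsort((1 - event, time))  # events before censorings at ties
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n = len(time)
    at_risk = n
    i = 0
    while i < n:
        t = time[i]
        d = 0
        c = 0
        while i < n and time[i] == t:
            if event[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append({"time": t, "n_at_risk": at_risk, "n_events": d, "survival": s})
        at_risk -= d + c
    return pd.DataFrame(rows)


def km_by_group(table: pd.DataFrame, labels: pd.Series) -> dict[str, pd.DataFrame]:
    out = {}
    for g in labels.unique():
        sel = labels == g
        out[g] = km_estimator(table.loc[sel, "time"].values, table.loc[sel, "event"].values)
    return out


def logrank_test(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> dict[str, float]:
    """k-group log-rank test; chi-square with k - 1 degrees of freedom.

    At each distinct event time the observed events per group are compared
    with the expectation under hypergeometric margins; the quadratic form of
    the summed (O - E) vector against its covariance gives the statistic.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        if (group == g).sum() == 0:
            raise ValueError(f"group {g} has no patients")
    if event.sum() == 0:
        raise ValueError("no events observed")

    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        d = int(((time == t) & (event == 1)).sum())
        n_i = np.array([(at_risk & (group == g)).sum() for g in labels], dtype=float)
        d_i = np.array(
            [((time == t) & (event == 1) & (group == g)).sum() for g in labels],
            dtype=float,
        )
        O += d_i
        E += d * n_i / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            p_i = n_i / n
            V += factor * (np.diag(p_i) - np.outer(p_i, p_i))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    return {"chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}


def logrank_from_table(table: pd.DataFrame, labels: pd.Series) -> dict[str, float]:
    return logrank_test(table["time"].values, table["event"].values, labels.values)
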