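"""Kaplan–Meier survival estimation and logrank comparison.

Used for repeated-shock survival experiments: subjects are cells, time
is the shock index (or minutes), status 1 marks death and 0 censoring.
The product-limit estimator and the Greenwood variance are computed
directly; the two-group logrank test is delegated to lifelines.
Deaths are processed before censorings at tied times (the standard
convention).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd


def km_estimate(table: pd.DataFrame) -> pd.DataFrame:
    """Kaplan–Meier survival curve with Greenwood standard errors.

    ``table`` has columns ``time`` and ``status`` (1 = death,
    0 = censored).  Returns one row per distinct death time with the
    number at risk, deaths, S(t) = Π(1 − dᵢ/nᵢ) and
    SE = S·sqrt(Σ dᵢ/[nᵢ(nᵢ − dᵢ)]).
    """
    if len(table) == 0:
        raise ValueError("empty survival table")
    times = np.asarray(table["time"], dtype=float)
    status = np.asarray(table["status"], dtype=int)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    death_times = np.unique(times[status == 1])
    s = 1.0
    gw = 0.0
    rows = []
    for t in death_times:
        # censored subjects at t are still at risk for deaths at t
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (status == 1)))
        s *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            gw += d / (n_at_risk * (n_at_risk - d))
            se = s * np.sqrt(gw)
        else:
            se = 0.0     # S has hit 0; Greenwood term degenerates
        rows.append({"time": t, "at_risk": n_at_risk, "deaths": d,
                     "survival": s, "se": se})
    if not rows:     # no deaths at all: flat S(t) = 1
        rows.append({"time": float(times.max()), "at_risk": len(times),
                     "deaths": 0, "survival": 1.0, "se": 0.0})
    return pd.DataFrame(rows)


def survival_at(km: pd.DataFrame, t: float) -> Tuple[float, float]:
    """(S(t), Greenwood SE) from a km_estimate table (stepwise)."""
    past = km[km["time"] <= t]
    if len(past) == 0:
        return 1.0, 0.0
    last = past.iloc[-1]
    return float(last["survival"]), float(last["se"])


def logrank(table_a: pd.DataFrame, table_b: pd.DataFrame
            ) -> Tuple[float, float]:
    """Two-group logrank test; returns (χ² statistic, p-value).

    With no deaths in either group the statistic is 0 and p = 1.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both groups must be non-empty")
    if (table_a["status"].sum() + table_b["status"].sum()) == 0:
        return 0.0, 1.0
    from lifelines.statistics import logrank_test
    res = logrank_test(table_a["time"], table_b["time"],
                       event_observed_A=table_a["status"],
                       event_observed_B=table_b["status"])
    return float(res.test_statistic), float(res.p_value)
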