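"""Survival and clinical-association statistics.

Kaplan-Meier product-limit curves, the two-group log-rank test,
Pearson chi-square contingency tests, and Spearman rank correlation.
KM and log-rank are implemented directly in numpy (the product-limit
estimator and the standard O-E / hypergeometric-variance statistic) so
they stay fast inside large calibration simulations; chi-square and
Spearman delegate to scipy. Tied event times use the simultaneous-event
convention and censoring at an event time is placed after the event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = ["KMCurve", "km_curve", "logrank_test", "contingency_chisq", "spearman"]


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray        # distinct event times, sorted
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # n at risk at each event time
    n_events: np.ndarray     # events at each event time

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise InputError("time and event must be equal-length 1-D")
    if len(t) < 1:
        raise InputError("need at least one record")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise InputError("times must be finite and positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise InputError("event flags must be 0/1")
    return t, e


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t, e = _as_arrays(time, event)
    event_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= et).sum() for et in event_times])
    d = np.array([((t == et) & (e == 1)).sum() for et in event_times])
    surv = np.cumprod(1.0 - d / at_risk) if len(event_times) else np.empty(0)
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk, n_events=d)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p).

    At each distinct pooled event time, O - E for group 1 is accumulated
    with the hypergeometric variance; the statistic U^2/V is referred to
    a chi-square distribution with 1 df.
    """
    t, e = _as_arrays(time, event)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise InputError("group must match time/event length")
    levels = np.unique(g)
    if len(levels) != 2:
        raise InputError(f"need exactly two groups, got {len(levels)}")
    in1 = g == levels[0]
    if e.sum() == 0:
        raise InputError("no events in either group")

    event_times = np.unique(t[e == 1])
    U = 0.0
    V = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        dying = (t == et) & (e == 1)
        d = dying.sum()
        d1 = (dying & in1).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = U * U / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def contingency_chisq(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test on an r x c count table.

    Continuity correction is off by default; returns (statistic, df, p).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise InputError("table must be at least 2x2")
    if np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise InputError("table entries must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise InputError("zero row or column margin")
    res = stats.chi2_contingency(obs, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InputError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InputError("undefined correlation for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
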