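"""Kaplan-Meier estimation and the log-rank test.

The product-limit estimator and the (O-E)^2/V log-rank statistic are
implemented directly so that every convention (at-risk counting, tie
handling, degrees of freedom) is explicit.  Samples censored exactly at an
event time are counted at risk for that event, the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .io_formats import ClinicalRecord
from .stats import TestResult

__all__ = ["SurvivalCurve", "km_estimate", "logrank_test", "filter_min_survival"]


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier product-limit curve.

    ``survival_probs[i]`` is the estimate just after ``event_times[i]``;
    ``at_risk[i]`` and ``n_events[i]`` are the risk-set size and death
    count at that time, and ``n_censored[i]`` counts censorings in the
    half-open interval between the previous event time (or 0) and this
    one, inclusive of this time.
    """

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any((self.survival_probs < 0) | (self.survival_probs > 1)):
            raise ValueError("survival probabilities outside [0, 1]")
        if np.any(np.diff(self.survival_probs) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t): step function evaluated at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D vector")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("times must be finite and >= 0")
    if np.any((e != 0) & (e != 1)):
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t, e = _check_times_events(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq_event_times = np.unique(t[e == 1])
    probs, at_risk, n_events, n_cens = [], [], [], []
    s = 1.0
    prev = -np.inf
    for ti in uniq_event_times:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (e == 1)))
        c_i = int(np.sum((t > prev) & (t <= ti) & (e == 0)))
        s *= 1.0 - d_i / n_i
        probs.append(s)
        at_risk.append(n_i)
        n_events.append(d_i)
        n_cens.append(c_i)
        prev = ti
    return SurvivalCurve(
        event_times=uniq_event_times,
        survival_probs=np.asarray(probs),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_events, dtype=int),
        n_censored=np.asarray(n_cens, dtype=int),
    )


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    group_labels: Sequence,
) -> TestResult:
    """Log-rank test across two or more groups (chi-square, k-1 df).

    At each distinct event time the observed group death counts are
    compared with their expectation under the pooled hazard; the variance
    is the multivariate hypergeometric covariance.  The statistic is the
    quadratic form of (O - E) over the first k-1 groups.
    """
    t, e = _check_times_events(times, events)
    labels = np.asarray(group_labels)
    if labels.shape != t.shape:
        raise ValueError("group_labels must match times in length")
    groups = np.unique(labels)
    k = groups.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if int(e.sum()) == 0:
        raise ValueError("need at least one event")
    gidx = np.searchsorted(groups, labels)
    uniq_event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for ti in uniq_event_times:
        at_risk_mask = t >= ti
        n = int(at_risk_mask.sum())
        d = int(np.sum((t == ti) & (e == 1)))
        n_g = np.bincount(gidx[at_risk_mask], minlength=k).astype(float)
        d_g = np.bincount(
            gidx[(t == ti) & (e == 1)], minlength=k
        ).astype(float)
        frac = n_g / n
        O += d_g
        E += d * frac
        if n > 1:
            scale = d * (n - d) / (n - 1)
            V += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p = float(chi2.sf(stat, df=k - 1))
    return TestResult(statistic=stat, p_value=p, n=t.size, method="logrank")


def filter_min_survival(
    records: Sequence[ClinicalRecord], min_months: float = 1.0
) -> list[ClinicalRecord]:
    """Drop samples with overall survival strictly below ``min_months``.

    A survival time of exactly ``min_months`` is retained.
    """
    return [r for r in records if r.os_months >= min_months]
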